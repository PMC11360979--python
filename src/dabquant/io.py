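"""Manifest handling, blinding bookkeeping and image I/O.

The analyst must not know group membership while placing and scoring
images, so the cohort manifest is shuffled with a seeded permutation and
stripped of its group column; a separately stored key inverts the blinding
exactly for the statistics stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd


@dataclass
class BlindingKey:
    """Bijection blinded_id ↔ (subject_id, group) plus the permutation seed."""

    table: pd.DataFrame  # columns: blinded_id, subject_id, group
    seed: int

    def unblind(self, blinded: pd.DataFrame) -> pd.DataFrame:
        """Restore subject_id and group to a blinded manifest/result table."""
        merged = blinded.merge(self.table, on="blinded_id", how="left", validate="m:1")
        if merged["subject_id"].isna().any():
            missing = blinded.loc[merged["subject_id"].isna(), "blinded_id"].tolist()
            raise ValueError(f"blinded ids not present in the key: {missing}")
        return merged

    def save(self, path: Union[str, Path]) -> None:
        out = self.table.copy()
        out["seed"] = self.seed
        out.to_csv(path, index=False)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "BlindingKey":
        df = pd.read_csv(path)
        seed = int(df["seed"].iloc[0]) if "seed" in df.columns else -1
        return cls(table=df[["blinded_id", "subject_id", "group"]], seed=seed)


def blind_manifest(manifest: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, BlindingKey]:
    """Shuffle a cohort manifest and strip its group column.

    Rows must be unique by subject_id. Returns the blinded manifest (rows in
    randomized presentation order, identified only by ``blinded_id``) and
    the key that inverts the blinding.
    """
    if manifest["subject_id"].duplicated().any():
        dups = manifest.loc[manifest["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dups}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(manifest))
    shuffled = manifest.iloc[perm].reset_index(drop=True)
    width = max(3, len(str(len(manifest))))
    blinded_ids = [f"B{i + 1:0{width}d}" for i in range(len(shuffled))]
    key = BlindingKey(
        table=pd.DataFrame(
            {
                "blinded_id": blinded_ids,
                "subject_id": shuffled["subject_id"].to_numpy(),
                "group": shuffled["group"].to_numpy(),
            }
        ),
        seed=seed,
    )
    blinded = shuffled.drop(columns=["group", "subject_id"])
    blinded.insert(0, "blinded_id", blinded_ids)
    return blinded, key


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read an 8-bit RGB TIFF or PNG; raises with the path on failure."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            img = tifffile.imread(path)
        else:
            from PIL import Image

            img = np.asarray(Image.open(path).convert("RGB"))
    except Exception as exc:  # pragma: no cover - message plumbing
        raise IOError(f"could not read image {path}: {exc}") from exc
    if img.ndim != 3 or img.shape[2] < 3:
        raise IOError(f"image {path} is not RGB (shape {img.shape})")
    return img[..., :3]


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "image_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    return df
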