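"""Comparative body-size data: species means, pooled variance, SEs.

Total length (TL) is analysed as log10 millimetres. Extant species carry
replicate TL measurements; fossil species carry a single skull measurement
(bizygomatic breadth, mm) from which log10(TL) is estimated by a published
allometric regression whose coefficients must be supplied (they are not
bundled). Measurement error enters downstream likelihoods as the standard
error of each species mean, computed from a variance pooled across all
species with replicate measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitDataset",
    "read_specimens",
    "estimate_log_length",
    "specimen_log_lengths",
    "species_means",
    "pooled_se",
]

SPECIMEN_COLUMNS = ("species", "TL_mm", "bizyg_mm")


@dataclass
class TraitDataset:
    """Per-species mean log10 total length with replicate counts and SEs."""

    species: list[str]
    mean: np.ndarray  # mean log10(TL), log10 mm
    n: np.ndarray  # replicate count per species, >= 1
    se: np.ndarray  # SE of the mean, log10 mm (>= 0)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.se = np.asarray(self.se, dtype=float)
        k = len(self.species)
        if not (self.mean.shape == self.n.shape == self.se.shape == (k,)):
            raise ValueError("field lengths disagree")
        if len(set(self.species)) != k:
            raise ValueError("duplicate species labels")
        if np.any(self.n < 1):
            raise ValueError("replicate counts must be >= 1")
        if np.any(self.se < 0):
            raise ValueError("negative SE")

    def __len__(self) -> int:
        return len(self.species)

    def align(self, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Trait means and SEs reordered to ``labels`` (e.g. tree tip order)."""
        pos = {s: i for i, s in enumerate(self.species)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise KeyError(f"no trait data for species: {missing}")
        idx = [pos[lab] for lab in labels]
        return self.mean[idx], self.se[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "mean_log10TL": self.mean,
                "n": self.n,
                "se": self.se,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitDataset":
        return cls(
            species=list(df["species"].astype(str)),
            mean=df["mean_log10TL"].to_numpy(float),
            n=df["n"].to_numpy(int),
            se=df["se"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path: str) -> "TraitDataset":
        return cls.from_frame(pd.read_csv(path))


def read_specimens(path: str) -> pd.DataFrame:
    """Read a specimen table CSV (species, TL_mm, bizyg_mm) and validate it.

    Each record must carry exactly one of TL_mm (a measured total length,
    extant specimens) or bizyg_mm (a fossil skull width), both strictly
    positive.
    """
    df = pd.read_csv(path)
    return validate_specimens(df)


def validate_specimens(df: pd.DataFrame) -> pd.DataFrame:
    for col in SPECIMEN_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"specimen table missing column {col!r}")
    has_tl = df["TL_mm"].notna()
    has_bz = df["bizyg_mm"].notna()
    bad = ~(has_tl ^ has_bz)
    if bad.any():
        raise ValueError(
            f"records must have exactly one of TL_mm / bizyg_mm; offending rows: "
            f"{list(df.index[bad])}"
        )
    if (df.loc[has_tl, "TL_mm"] <= 0).any() or (df.loc[has_bz, "bizyg_mm"] <= 0).any():
        raise ValueError("lengths and skull widths must be strictly positive")
    return df


def estimate_log_length(bizyg, coef) -> np.ndarray | float:
    """Estimated log10 total length (mm) from bizygomatic breadth (mm).

    The estimate is the affine function ``intercept + slope * log10(bizyg)``.
    ``coef`` is ``(intercept, slope)``; the published regression coefficients
    are not bundled and must be supplied from the source regression.
    """
    if coef is None:
        raise ValueError(
            "no regression coefficients: supply (intercept, slope) transcribed "
            "from the published skull-width/total-length regression"
        )
    intercept, slope = float(coef[0]), float(coef[1])
    b = np.asarray(bizyg, dtype=float)
    if np.any(b <= 0):
        raise ValueError("bizygomatic breadth must be strictly positive")
    out = intercept + slope * np.log10(b)
    return float(out) if np.isscalar(bizyg) else out


def specimen_log_lengths(specimens: pd.DataFrame, coef=None) -> pd.DataFrame:
    """Per-record log10(TL): measured lengths directly, fossils via regression.

    Returns columns species, log10TL, estimated (bool).
    """
    df = validate_specimens(specimens)
    has_tl = df["TL_mm"].notna()
    log10tl = np.empty(len(df))
    log10tl[has_tl.to_numpy()] = np.log10(df.loc[has_tl, "TL_mm"].to_numpy(float))
    if (~has_tl).any():
        log10tl[(~has_tl).to_numpy()] = estimate_log_length(
            df.loc[~has_tl, "bizyg_mm"].to_numpy(float), coef
        )
    return pd.DataFrame(
        {
            "species": df["species"].astype(str).to_numpy(),
            "log10TL": log10tl,
            "estimated": (~has_tl).to_numpy(),
        }
    )


def species_means(specimens: pd.DataFrame, coef=None) -> TraitDataset:
    """Arithmetic mean of log10(TL) per species, with replicate counts.

    SEs are set to zero; use :func:`pooled_se` to attach pooled-variance SEs.
    """
    logs = specimen_log_lengths(specimens, coef=coef)
    if logs.empty:
        raise ValueError("empty specimen table")
    g = logs.groupby("species", sort=True)["log10TL"]
    mean = g.mean()
    n = g.size()
    return TraitDataset(
        species=list(mean.index),
        mean=mean.to_numpy(),
        n=n.to_numpy(),
        se=np.zeros(len(mean)),
    )


def pooled_se(specimens: pd.DataFrame, coef=None) -> TraitDataset:
    """Species means with SEs from a variance pooled over replicated species.

    The pooled variance is ``s²_p = Σ (n_i − 1) s²_i / Σ (n_i − 1)`` over all
    species with n_i > 1, computed on log10 lengths; every species — including
    single-specimen fossils — then gets ``se_i = s_p / sqrt(n_i)``.
    """
    logs = specimen_log_lengths(specimens, coef=coef)
    g = logs.groupby("species", sort=True)["log10TL"]
    n = g.size()
    var = g.var(ddof=1)  # NaN for n=1 groups
    multi = n > 1
    if not multi.any():
        raise ValueError(
            "pooled variance undefined: no species has more than one specimen"
        )
    w = (n[multi] - 1).to_numpy(float)
    s2p = float(np.sum(w * var[multi].to_numpy()) / np.sum(w))
    sp = np.sqrt(s2p)
    ds = species_means(specimens, coef=coef)
    ds.se = sp / np.sqrt(ds.n.astype(float))
    return ds
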