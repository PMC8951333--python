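"""Plasma-EV sample bookkeeping: QC, dosing, pooling and normalization.

Covers the sample-handling conventions of a crossover conditioning
study (remote ischemic conditioning and resistance-exercise groups,
plus non-intervention controls) with blood drawn before and at several
timepoints after intervention:

* hemolysis QC — plasma is discarded when free-hemoglobin absorbance at
  414 nm exceeds 0.2, and a subject is retained only if *all* of their
  timepoints pass;
* within-subject dose equalization — every timepoint is diluted down to
  the subject's lowest EV concentration so identical particle numbers
  are used across timepoints;
* pooling of per-subject isolates into group/timepoint lots;
* post/pre normalization of assay readouts within each subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlasmaSample",
    "HEMOLYSIS_A414_MAX",
    "hemolysis_filter",
    "equalize_dose",
    "pool_samples",
    "normalize_to_pre",
]

#: QC gate: free-hemoglobin absorbance above this discards the sample.
HEMOLYSIS_A414_MAX = 0.2

GROUPS = ("NIC", "RIC", "BFRRE", "HLRE")
TIMEPOINTS = ("pre", "5min", "30min", "6wk")


@dataclass(frozen=True)
class PlasmaSample:
    """One plasma EV isolate: subject x timepoint with QC and yield data."""

    subject: str
    group: str
    timepoint: str
    a414: float
    concentration: float  # particles/mL
    volume_ml: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.a414 < 0 or self.concentration < 0 or self.volume_ml < 0:
            raise ValueError("A414, concentration and volume must be nonnegative")


def _as_table(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples.copy()
    return pd.DataFrame([vars(s) for s in samples])


def hemolysis_filter(samples) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split samples into (kept, discarded) by the hemolysis gate.

    A sample fails if its A414 exceeds 0.2 (exactly 0.2 passes) or is
    missing. A subject is kept only if every one of their timepoints
    passes; all samples of any failing subject are discarded.
    """
    df = _as_table(samples)
    a414 = pd.to_numeric(df["a414"], errors="coerce")
    sample_pass = a414.notna() & (a414 <= HEMOLYSIS_A414_MAX)
    subject_pass = sample_pass.groupby(df["subject"]).transform("all")
    kept = df[subject_pass].reset_index(drop=True)
    discarded = df[~subject_pass].reset_index(drop=True)
    return kept, discarded


def equalize_dose(samples) -> pd.DataFrame:
    """Within-subject dilution plan equalizing EV dose across timepoints.

    For each subject, every timepoint is diluted by
    ``concentration / min(concentration over timepoints)`` so the
    effective concentration equals the subject's minimum; the lowest
    timepoint keeps factor 1. All factors are >= 1 (dilution only).
    """
    df = _as_table(samples)
    if (df["concentration"] <= 0).any():
        raise ValueError("all EV concentrations must be positive to plan doses")
    min_conc = df.groupby("subject")["concentration"].transform("min")
    df["dilution_factor"] = df["concentration"] / min_conc
    df["effective_concentration"] = df["concentration"] / df["dilution_factor"]
    return df


def pool_samples(
    samples, group: str, timepoint: str, mode: str = "equal_particles"
) -> dict[str, float]:
    """Pool per-subject isolates of one group x timepoint into a lot.

    ``mode='equal_particles'`` (default): each subject contributes the
    same particle number, capped by the least-endowed sample (volume
    drawn per subject is that particle number over the subject's
    concentration). ``mode='full_volume'``: entire sample volumes are
    combined. Particle counts are conserved in both modes.
    """
    df = _as_table(samples)
    if not ((df["group"] == group) & (df["timepoint"] == timepoint)).all():
        raise ValueError("pooling requires a single group and timepoint")
    if df.empty:
        raise ValueError("no samples to pool")
    conc = df["concentration"].to_numpy(dtype=float)
    vol = df["volume_ml"].to_numpy(dtype=float)
    if mode == "equal_particles":
        if (conc <= 0).any():
            raise ValueError("equal-particle pooling needs positive concentrations")
        per_subject = float((conc * vol).min())
        volumes = per_subject / conc
        total = per_subject * len(df)
    elif mode == "full_volume":
        volumes = vol
        total = float((conc * vol).sum())
    else:
        raise ValueError("mode must be 'equal_particles' or 'full_volume'")
    pooled_volume = float(volumes.sum())
    return {
        "total_particles": total,
        "volume_ml": pooled_volume,
        "concentration": total / pooled_volume if pooled_volume > 0 else 0.0,
        "n_subjects": int(len(df)),
    }


def normalize_to_pre(readouts: pd.DataFrame, pre_label: str = "pre") -> pd.DataFrame:
    """Normalize each subject's readouts to their pre-intervention value.

    Input columns: ``subject, timepoint, value`` (extra columns pass
    through). Adds ``normalized`` = value / value(pre); the pre timepoint
    maps to exactly 1. Subjects without a usable (nonzero) pre value are
    excluded with a warning.
    """
    df = readouts.copy()
    pre = (
        df[df["timepoint"] == pre_label]
        .set_index("subject")["value"]
        .rename("pre_value")
    )
    df = df.join(pre, on="subject")
    bad = df["pre_value"].isna() | (df["pre_value"] == 0)
    if bad.any():
        dropped = sorted(df.loc[bad, "subject"].unique())
        warnings.warn(f"subjects without usable pre value excluded: {dropped}",
                      stacklevel=2)
        df = df[~bad]
    df["normalized"] = df["value"] / df["pre_value"]
    df.loc[df["timepoint"] == pre_label, "normalized"] = 1.0
    return df.drop(columns="pre_value").reset_index(drop=True)
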