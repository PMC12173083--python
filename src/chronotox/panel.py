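"""Three-step multiplex-panel normalisation (nCounter-style).

Raw probe counts per lane are normalised in a fixed order:

1. positive-control scaling  — each lane is rescaled so its positive-control
   arithmetic mean matches the across-lane reference (the arithmetic mean of
   the per-lane positive-control means);
2. background subtraction    — the lane's negative-control arithmetic mean is
   subtracted from every non-negative-control probe, floored at a configured
   minimum (default 1 so a log2 transform stays defined);
3. housekeeping normalisation — each lane is rescaled so the geometric mean of
   its housekeeping probes matches the across-lane reference geometric mean.

The order is part of the contract and must not be permuted.  A log2 transform
follows for downstream differential analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PROBE_CLASSES",
    "PanelCountMatrix",
    "positive_control_scale",
    "negative_control_subtract",
    "housekeeping_normalise",
    "log2_transform",
    "normalise_panel",
]

PROBE_CLASSES = ("positive", "negative", "housekeeping", "endogenous")


@dataclass
class PanelCountMatrix:
    """Lane x probe count matrix with a probe-class annotation.

    ``counts`` is a DataFrame indexed by lane id with one column per probe;
    ``probe_class`` maps each probe id to one of :data:`PROBE_CLASSES`.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    flagged_lanes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.probe_class = self.probe_class.reindex(self.counts.columns)
        unknown = set(self.probe_class.dropna().unique()) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        if self.probe_class.isna().any():
            missing = list(self.counts.columns[self.probe_class.isna()])
            raise ValueError(f"probes without a class annotation: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def probes_of(self, cls: str) -> list[str]:
        return list(self.probe_class.index[self.probe_class == cls])

    def require(self, cls: str) -> list[str]:
        probes = self.probes_of(cls)
        if not probes:
            raise ValueError(f"matrix has no {cls!r} probes")
        return probes

    def copy(self) -> "PanelCountMatrix":
        return PanelCountMatrix(
            self.counts.copy(), self.probe_class.copy(), dict(self.flagged_lanes)
        )

    @classmethod
    def from_tidy(cls, table: pd.DataFrame) -> "PanelCountMatrix":
        """Build from a tidy table with columns lane_id, probe_id, probe_class, count."""
        required = {"lane_id", "probe_id", "probe_class", "count"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"tidy panel table missing columns: {sorted(missing)}")
        wide = table.pivot(index="lane_id", columns="probe_id", values="count")
        classes = (
            table.drop_duplicates("probe_id").set_index("probe_id")["probe_class"]
        )
        return cls(wide, classes.reindex(wide.columns))

    def to_tidy(self) -> pd.DataFrame:
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["lane_id", "probe_id", "count"]
        long["probe_class"] = long["probe_id"].map(self.probe_class)
        return long[["lane_id", "probe_id", "probe_class", "count"]]


def positive_control_scale(
    matrix: PanelCountMatrix,
) -> tuple[PanelCountMatrix, pd.Series]:
    """Step 1: scale every lane by its positive-control factor.

    factor = (across-lane mean of lane positive-control means) / (lane mean).
    Lanes whose positive-control mean is zero cannot be scaled; they are
    flagged, left unscaled, excluded from the reference, and a warning is
    emitted.
    """
    out = matrix.copy()
    pos = matrix.require("positive")
    lane_means = matrix.counts[pos].mean(axis=1)
    usable = lane_means > 0
    if not usable.any():
        raise ValueError("no lane has a positive positive-control mean")
    reference = lane_means[usable].mean()
    factors = pd.Series(np.nan, index=matrix.counts.index, name="positive_factor")
    factors[usable] = reference / lane_means[usable]
    for lane in lane_means.index[~usable]:
        out.flagged_lanes[lane] = "zero positive-control mean"
        warnings.warn(f"lane {lane!r}: zero positive-control mean, not scaled")
    out.counts.loc[usable] = out.counts.loc[usable].mul(factors[usable], axis=0)
    return out, factors


def negative_control_subtract(
    matrix: PanelCountMatrix, floor: float = 1.0
) -> PanelCountMatrix:
    """Step 2: subtract each lane's negative-control mean as background.

    The subtraction applies to every probe that is not itself a negative
    control; results are floored at ``floor``.
    """
    out = matrix.copy()
    neg = matrix.require("negative")
    background = matrix.counts[neg].mean(axis=1)
    target = [p for p in matrix.counts.columns if matrix.probe_class[p] != "negative"]
    adjusted = out.counts[target].sub(background, axis=0).clip(lower=floor)
    out.counts[target] = adjusted
    return out


def housekeeping_normalise(
    matrix: PanelCountMatrix,
) -> tuple[PanelCountMatrix, pd.Series]:
    """Step 3: scale lanes so housekeeping geometric means agree.

    factor = (across-lane mean of lane housekeeping geometric means) /
    (lane geometric mean).  Applies to housekeeping and endogenous probes
    (controls have served their purpose).  Lanes with a non-positive
    housekeeping value are flagged and left unscaled.
    """
    out = matrix.copy()
    hk = matrix.require("housekeeping")
    hk_counts = matrix.counts[hk]
    usable = (hk_counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no lane has all-positive housekeeping counts")
    geomeans = pd.Series(np.nan, index=matrix.counts.index)
    geomeans[usable] = np.exp(np.log(hk_counts[usable]).mean(axis=1))
    reference = geomeans[usable].mean()
    factors = pd.Series(np.nan, index=matrix.counts.index, name="housekeeping_factor")
    factors[usable] = reference / geomeans[usable]
    for lane in matrix.counts.index[~usable]:
        out.flagged_lanes[lane] = "non-positive housekeeping count"
        warnings.warn(f"lane {lane!r}: non-positive housekeeping count, not scaled")
    target = [
        p
        for p in matrix.counts.columns
        if matrix.probe_class[p] in ("housekeeping", "endogenous")
    ]
    out.counts.loc[usable, target] = out.counts.loc[usable, target].mul(
        factors[usable], axis=0
    )
    return out, factors


def log2_transform(matrix: PanelCountMatrix, pseudo: float = 0.0) -> PanelCountMatrix:
    """log2(count + pseudo).  With the default background floor of 1 upstream,
    ``pseudo=0`` is safe; use ``pseudo=1`` when the floor is below 1."""
    out = matrix.copy()
    vals = out.counts.to_numpy() + pseudo
    if (vals <= 0).any():
        raise ValueError("non-positive values under log2; raise `pseudo` or the floor")
    out.counts = pd.DataFrame(
        np.log2(vals), index=out.counts.index, columns=out.counts.columns
    )
    return out


def normalise_panel(
    matrix: PanelCountMatrix,
    background_floor: float = 1.0,
    log2: bool = True,
    pseudo: float = 0.0,
    batch: pd.Series | None = None,
) -> tuple[PanelCountMatrix, dict]:
    """Run the full pipeline: positive -> negative -> housekeeping [-> batch] [-> log2].

    Returns the normalised matrix and a metadata dict recording the per-lane
    factors and settings.  ``batch`` (lane -> batch label) enables an
    experimental per-batch mean-centring of log2 endogenous values; it is off
    by default and the centring method is a package choice, not a vendor
    convention.
    """
    step1, pos_factors = positive_control_scale(matrix)
    step2 = negative_control_subtract(step1, floor=background_floor)
    step3, hk_factors = housekeeping_normalise(step2)
    result = log2_transform(step3, pseudo=pseudo) if log2 else step3
    meta = {
        "positive_factors": pos_factors.to_dict(),
        "housekeeping_factors": hk_factors.to_dict(),
        "background_floor": background_floor,
        "log2": log2,
        "pseudo": pseudo,
        "flagged_lanes": dict(result.flagged_lanes),
        "batch_corrected": False,
    }
    if batch is not None:
        if not log2:
            raise ValueError("batch centring is defined on the log2 scale")
        endo = result.probes_of("endogenous")
        grouped = result.counts[endo].groupby(batch.reindex(result.counts.index))
        centred = result.counts[endo] - grouped.transform("mean") + result.counts[endo].mean()
        result.counts[endo] = centred
        meta["batch_corrected"] = True
    return result, meta
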