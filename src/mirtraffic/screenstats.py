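"""Hit calling for fluorescence-microscopy ligand-uptake screens.

Raw readout: one median ligand-uptake intensity per well (the median over
all segmented cells in that well's images).  Within each experimental
replicate the wells are normalized to the negative controls:

    score = (median_uptake - median(NC)) / SD(NC)

where NC are the negative-control wells of that experiment and SD is the
sample standard deviation of their well values.  Positive scores mean
facilitated internalisation, negative scores inhibition.

Scores are averaged across experiments per condition and compared with a
ligand-specific threshold: half the normalized positive-control score
(+/-1 for DiI-LDL, +/-2 for EGF), except transferrin where a fixed +/-2
is used because receptor recycling leaves plasma-membrane signal that
inflates the positive-control scale.  Significance is a two-sided
one-sample t-test of the replicate scores against 0; a sub-threshold
condition with p <= 0.01 may still be scored as a hit (always annotated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Role = Literal["negative_control", "positive_control", "test"]

ALPHA = 0.05
#: p-value required to promote a sub-threshold effect to a hit
SUBTHRESHOLD_ALPHA = 0.01
#: fixed threshold for the transferrin assay (recycling cargo)
TRANSFERRIN_THRESHOLD = 2.0


@dataclass
class WellMeasurement:
    well: str
    condition: str
    role: Role
    replicate: int
    median_uptake: float | None  # None flags a well with no cells

    @property
    def missing(self) -> bool:
        return self.median_uptake is None or not np.isfinite(self.median_uptake)


@dataclass
class NormalizedScore:
    condition: str
    role: Role
    replicate: int
    score: float


@dataclass
class HitCall:
    condition: str
    mean_score: float
    threshold: float
    verdict: Literal["inhibition", "facilitation", "none"]
    p_value: float | None
    significant: bool
    subthreshold_significant: bool = False
    degenerate: bool = False
    n_replicates: int = 0


@dataclass
class RescueRecord:
    bin_label: str
    n_cells: int
    mean_uptake: float


class DegenerateControlsError(ValueError):
    """Negative-control wells have zero spread; scores are undefined."""


def normalize_to_controls(wells: Sequence[WellMeasurement]) -> list[NormalizedScore]:
    """Normalize one experiment's well medians to its negative controls.

    Requires >= 2 non-missing negative-control wells.  By construction the
    negative-control scores themselves come out with median 0 and sample
    SD 1 exactly.
    """
    nc = [w.median_uptake for w in wells if w.role == "negative_control" and not w.missing]
    if len(nc) < 2:
        raise ValueError("need at least 2 negative-control wells with values")
    nc = np.asarray(nc, dtype=float)
    center = np.median(nc)
    sd = nc.std(ddof=1)
    if sd == 0:
        raise DegenerateControlsError("negative-control wells have zero SD")
    return [
        NormalizedScore(w.condition, w.role, w.replicate, (w.median_uptake - center) / sd)
        for w in wells
        if not w.missing
    ]


def normalize_experiments(
    wells: Iterable[WellMeasurement],
) -> list[NormalizedScore]:
    """Normalize each experimental replicate separately, then pool scores."""
    by_rep: dict[int, list[WellMeasurement]] = {}
    for w in wells:
        by_rep.setdefault(w.replicate, []).append(w)
    scores: list[NormalizedScore] = []
    for rep in sorted(by_rep):
        scores.extend(normalize_to_controls(by_rep[rep]))
    return scores


def derive_threshold(
    positive_control_score: float | None,
    ligand: str = "ldl",
    transferrin_threshold: float = TRANSFERRIN_THRESHOLD,
) -> float:
    """Ligand-specific hit threshold.

    Half the |positive-control score|, except transferrin (``tfn``) where a
    fixed configured threshold is used regardless of the positive control.
    """
    if ligand.lower() in ("tfn", "transferrin"):
        return transferrin_threshold
    if positive_control_score is None:
        raise ValueError(f"ligand {ligand!r} needs a positive-control score")
    return abs(positive_control_score) / 2.0


def call_hits(
    scores: Iterable[NormalizedScore],
    threshold: float,
    alpha: float = ALPHA,
    subthreshold_alpha: float = SUBTHRESHOLD_ALPHA,
) -> list[HitCall]:
    """Threshold + t-test hit calls, one per condition.

    The across-replicate *mean* score is compared with +/-threshold
    (boundary inclusive).  p is from a two-sided one-sample t-test of the
    replicate scores against 0 (None with a single replicate).  A condition
    whose |mean| is below threshold but whose p <= ``subthreshold_alpha``
    is still called, with ``subthreshold_significant`` set.
    """
    by_cond: dict[str, list[float]] = {}
    for s in scores:
        by_cond.setdefault(s.condition, []).append(s.score)
    calls = []
    for cond in sorted(by_cond):
        vals = np.asarray(by_cond[cond], dtype=float)
        mean = float(vals.mean())
        degenerate = False
        if vals.size < 2:
            p = None
        elif vals.std(ddof=1) == 0:
            p = 0.0 if mean != 0 else 1.0
            degenerate = True
        else:
            p = float(stats.ttest_1samp(vals, 0.0).pvalue)
        significant = p is not None and p <= alpha
        sub = False
        if abs(mean) >= threshold:
            verdict = "inhibition" if mean < 0 else "facilitation"
        elif p is not None and p <= subthreshold_alpha:
            verdict = "inhibition" if mean < 0 else "facilitation"
            sub = True
        else:
            verdict = "none"
        calls.append(
            HitCall(cond, mean, threshold, verdict, p, significant, sub, degenerate, vals.size)
        )
    return calls


def rescue_index(
    cells: pd.DataFrame,
    reference_cells: pd.DataFrame,
    n_bins: int = 4,
    bin_edges: Sequence[float] | None = None,
    uptake_col: str = "ligand_intensity",
    marker_col: str = "marker_intensity",
) -> dict:
    """Marker-expression-binned rescue quantification.

    ``cells`` carry a rescue-construct marker; they are split into
    sub-populations by marker intensity (quartiles by default, or explicit
    ``bin_edges``) and the mean ligand uptake per bin is reported.  The
    rescue index is the highest bin's mean uptake divided by the mean
    uptake of the whole reference population (cells expressing the inert
    control construct).  Per-bin means expose the concentration dependence
    of the rescue.
    """
    if reference_cells.empty:
        raise ValueError("reference population is empty")
    marker = cells[marker_col].to_numpy(dtype=float)
    if bin_edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.quantile(marker, qs)
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.searchsorted(edges, marker, side="right") - 1, 0, len(edges) - 2)
    bins = []
    for b in range(len(edges) - 1):
        sel = cells.loc[idx == b, uptake_col]
        if len(sel) == 0:
            continue
        bins.append(
            RescueRecord(f"[{edges[b]:.3g}, {edges[b + 1]:.3g})", len(sel), float(sel.mean()))
        )
    ref_mean = float(reference_cells[uptake_col].mean())
    high_mean = bins[-1].mean_uptake if bins else None
    return {
        "bins": bins,
        "reference_mean": ref_mean,
        "rescue_index": None if high_mean is None else high_mean / ref_mean,
        "monotone_increasing": all(
            bins[i].mean_uptake <= bins[i + 1].mean_uptake for i in range(len(bins) - 1)
        )
        if len(bins) > 1
        else None,
    }


def scores_frame(scores: Iterable[NormalizedScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"condition": s.condition, "role": s.role, "replicate": s.replicate, "score": s.score} for s in scores]
    )


def hits_frame(calls: Iterable[HitCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": c.condition,
                "mean_score": c.mean_score,
                "threshold": c.threshold,
                "verdict": c.verdict,
                "p": c.p_value,
                "significant": c.significant,
                "subthreshold_significant": c.subthreshold_significant,
            }
            for c in calls
        ]
    )
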