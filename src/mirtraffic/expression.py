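"""Probe-level expression processing and qPCR relative quantification.

The microarray chain mirrors a bead-array workflow with duplicate arrays
per condition and time point and many probes per transcript:

1. per transcript within each array, drop outlier probes whose absolute
   deviation from the probe median exceeds 2.5 median absolute deviations
   (MAD, unscaled);
2. average the retained probe intensities per transcript per array;
3. quantile-normalize the transcript x array matrix;
4. fold change = ratio of mean test intensity to mean control intensity,
   reported as a *signed linear* value: r if r >= 1, else -1/r, so that
   -2.0 means halved expression and |FC| >= 1 always;
5. an array dispersion statistic: (test mean - control mean) divided by
   the sum of the replicate standard deviations of the two groups.

Transcripts pass a threshold (1.5- or 1.8-fold) when |FC| >= threshold.

qPCR quantification uses the 2^-ddCt method: dCt = Ct_target - Ct_reference
per condition (technical replicates averaged first), ddCt = dCt_test -
dCt_control, relative expression = 2^-ddCt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

MAD_CUTOFF = 2.5
#: absolute fallback tolerance when the MAD is exactly zero
ZERO_MAD_EPS = 1e-9

TIMEPOINTS = (12, 24, 48)


@dataclass
class FoldChangeRecord:
    transcript_id: str
    timepoint: int
    fold_change: float  # signed linear, |FC| >= 1
    array_sd_stat: float | None

    @property
    def passes_1p5(self) -> bool:
        return abs(self.fold_change) >= 1.5

    @property
    def passes_1p8(self) -> bool:
        return abs(self.fold_change) >= 1.8


def filter_outlier_probes(values, cutoff: float = MAD_CUTOFF) -> np.ndarray:
    """Drop values whose |x - median| / MAD exceeds ``cutoff``.

    The MAD is the *unscaled* median absolute deviation from the median
    (no 1.4826 normal-consistency factor).  When the MAD is zero (at least
    half the values identical) any value deviating by more than a small
    absolute epsilon is removed and the event logged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        return x
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    if mad == 0:
        keep = dev <= ZERO_MAD_EPS
        if not keep.all():
            logger.info(
                "zero-MAD fallback removed %d of %d probes", (~keep).sum(), x.size
            )
    else:
        keep = dev / mad <= cutoff
    return x[keep]


def summarize_probes(
    probes: pd.DataFrame,
    array_columns: list[str] | None = None,
    cutoff: float = MAD_CUTOFF,
) -> pd.DataFrame:
    """Outlier-filter and average probes per transcript per array.

    ``probes`` has a ``transcript_id`` column (and optionally ``probe_id``);
    every other column — or ``array_columns`` if given — is one array of
    raw probe intensities.  Returns a transcript x array matrix of means
    over retained probes.  Transcripts whose probes are *all* removed on
    some array get NaN there and a log entry.
    """
    if array_columns is None:
        array_columns = [c for c in probes.columns if c not in ("probe_id", "transcript_id")]
    out = {}
    for tid, grp in probes.groupby("transcript_id", sort=True):
        row = {}
        for col in array_columns:
            retained = filter_outlier_probes(grp[col].to_numpy(), cutoff)
            if retained.size == 0:
                logger.warning("transcript %s: all probes removed on array %s", tid, col)
                row[col] = np.nan
            else:
                row[col] = retained.mean()
        out[tid] = row
    return pd.DataFrame.from_dict(out, orient="index")[array_columns]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions across columns (arrays).

    Each column's sorted values are replaced by the across-column mean of
    sorted values; ties within a column receive the average of the target
    values at their tied ranks.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    values = matrix.to_numpy(dtype=float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average") - 1  # 0-based, ties averaged
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (target[lo] + target[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def signed_fold_change(test_mean: float, control_mean: float) -> float:
    """Signed linear fold change: r = test/control, reported as r or -1/r.

    >>> signed_fold_change(50, 100)
    -2.0
    """
    if test_mean <= 0 or control_mean <= 0:
        raise ValueError("means must be positive for a linear fold change")
    r = test_mean / control_mean
    return r if r >= 1 else -1.0 / r


def array_sd_stat(
    test_mean: float, control_mean: float, sd_test: float, sd_control: float
) -> float | None:
    """(test - control) / (sd_test + sd_control); None when degenerate.

    A zero denominator (no replicate variance in either group) makes the
    effect size infinite; such records are flagged degenerate (None) and
    logged rather than propagated.
    """
    denom = sd_test + sd_control
    if denom <= 0:
        # routine after quantile normalization: a transcript holding the
        # same rank on every array gets identical values
        logger.info("array_sd_stat degenerate: zero replicate variance")
        return None
    return (test_mean - control_mean) / denom


def fold_changes(
    summarized: pd.DataFrame,
    design: pd.DataFrame,
    normalize: bool = True,
) -> list[FoldChangeRecord]:
    """Full chain from summarized probes to per-timepoint fold changes.

    ``summarized`` is a transcript x array matrix (as from
    :func:`summarize_probes`); ``design`` maps each array column to
    ``condition`` ('test' or 'control'), ``timepoint`` (h) and ``replicate``.
    Quantile normalization is applied across all arrays before ratios.
    """
    design = design.set_index("array") if "array" in design.columns else design
    mat = quantile_normalize(summarized) if normalize else summarized
    records: list[FoldChangeRecord] = []
    for tp in sorted(design["timepoint"].unique()):
        test_cols = design.index[(design.condition == "test") & (design.timepoint == tp)]
        ctrl_cols = design.index[(design.condition == "control") & (design.timepoint == tp)]
        if len(test_cols) == 0 or len(ctrl_cols) == 0:
            raise ValueError(f"timepoint {tp}: missing test or control arrays")
        for tid in mat.index:
            t = mat.loc[tid, test_cols].to_numpy(dtype=float)
            c = mat.loc[tid, ctrl_cols].to_numpy(dtype=float)
            if np.isnan(t).any() or np.isnan(c).any():
                logger.warning("transcript %s at %sh: missing summarized value", tid, tp)
                continue
            fc = signed_fold_change(t.mean(), c.mean())
            stat = array_sd_stat(t.mean(), c.mean(), t.std(ddof=1), c.std(ddof=1))
            records.append(FoldChangeRecord(str(tid), int(tp), fc, stat))
    return records


def select_regulated(
    records: list[FoldChangeRecord], threshold: float = 1.5
) -> dict:
    """Per-timepoint up/down hit lists at |FC| >= threshold, plus the union.

    The union counts each transcript once even when it passes at several
    time points.
    """
    if threshold < 1:
        raise ValueError("threshold is a linear fold, must be >= 1")
    per_tp: dict[int, dict[str, list[str]]] = {}
    union: dict[str, None] = {}  # insertion-ordered set
    for rec in records:
        if abs(rec.fold_change) < threshold:
            continue
        tp = per_tp.setdefault(rec.timepoint, {"up": [], "down": []})
        tp["up" if rec.fold_change > 0 else "down"].append(rec.transcript_id)
        union.setdefault(rec.transcript_id)
    return {"per_timepoint": per_tp, "union": list(union)}


def relative_expression_ddct(ct: pd.DataFrame) -> dict:
    """2^-ddCt relative expression from a Ct table.

    ``ct`` columns: ``sample`` (optional), ``gene`` in {'target','reference'},
    ``condition`` in {'test','control'}, ``ct``, ``replicate`` (optional).
    Technical replicates are averaged before dCt.  Returns a dict with
    ``delta_delta_ct`` and ``relative_expression``.
    """
    needed = {"gene", "condition", "ct"}
    if not needed <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(needed)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    means = ct.groupby(["condition", "gene"])["ct"].mean()
    try:
        dct_test = means[("test", "target")] - means[("test", "reference")]
        dct_ctrl = means[("control", "target")] - means[("control", "reference")]
    except KeyError as e:
        raise ValueError(f"missing Ct group: {e}") from e
    ddct = dct_test - dct_ctrl
    return {"delta_delta_ct": float(ddct), "relative_expression": float(2.0 ** -ddct)}
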