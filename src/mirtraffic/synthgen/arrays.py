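"""Synthetic bead-array probe matrices and qPCR Ct tables.

The probe model: intensity = transcript baseline x planted fold (test
arrays only) x bead affinity x array scale x lognormal noise, with a
small rate of gross outlier probes (large multiplicative deviations, the
kind the MAD-2.5 filter is meant to remove).  Each condition/time point
is measured on duplicate arrays.  The "probes" of one transcript emulate
replicate beads carrying the same probe sequence, so their affinity
spread is small (bead position effects) while bead-level measurement
noise dominates; array-wide scale factors emulate labelling/scanner
differences and are what quantile normalization removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIMEPOINTS = (12, 24, 48)


@dataclass
class ExpressionSpec:
    n_transcripts: int = 200
    probes_per_transcript: int = 26
    timepoints: tuple = TIMEPOINTS
    replicates: int = 2  # arrays per condition per time point
    planted_fold_changes: dict = field(default_factory=dict)  # (tid, tp) -> linear ratio
    outlier_probe_rate: float = 0.02
    outlier_factor: float = 8.0
    probe_noise_sd: float = 0.2  # lognormal sigma of per-bead measurement noise
    affinity_sd: float = 0.05  # lognormal sigma of per-bead position/affinity effects
    array_scale_sd: float = 0.1  # lognormal sigma of per-array global scale
    baseline_log_mean: float = np.log(500.0)
    baseline_log_sd: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.probes_per_transcript < 1:
            raise ValueError("need at least one probe per transcript")
        if self.replicates < 2:
            raise ValueError("each condition requires duplicate arrays")
        if not 0 <= self.outlier_probe_rate < 1:
            raise ValueError("outlier_probe_rate must be in [0, 1)")


def array_columns(spec: ExpressionSpec) -> pd.DataFrame:
    """The array design: one row per array column with condition/timepoint/replicate."""
    rows = []
    for tp in spec.timepoints:
        for cond in ("test", "control"):
            for rep in range(1, spec.replicates + 1):
                rows.append(
                    {
                        "array": f"{cond}_{tp}h_r{rep}",
                        "condition": cond,
                        "timepoint": tp,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def make_expression_dataset(spec: ExpressionSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(probes, design, truth)``.

    * ``probes`` — probe_id, transcript_id, one intensity column per array;
    * ``design`` — array annotation (condition, timepoint, replicate);
    * ``truth`` — planted linear fold per (transcript, timepoint), 1.0
      where nothing was planted.
    """
    rng = np.random.default_rng(spec.rng_seed)
    design = array_columns(spec)
    tids = [f"TX{i + 1:04d}" for i in range(spec.n_transcripts)]
    regulated = {tid for (tid, _tp), f in spec.planted_fold_changes.items() if f != 1.0}
    z = rng.normal(size=spec.n_transcripts)
    for i, tid in enumerate(tids):
        # regulated transcripts sit inside the quantifiable dynamic range:
        # a fold change of a floor-level transcript is unmeasurable by
        # rank-based normalization and the extreme brightest signals
        # saturate the scanner; real hit lists come from in-range signals
        while tid in regulated and not -1.0 <= z[i] <= 2.0:
            z[i] = rng.normal()
    baselines = np.exp(spec.baseline_log_mean + spec.baseline_log_sd * z)
    rows = []
    truth_rows = []
    for tid, base in zip(tids, baselines):
        affin = rng.lognormal(0.0, spec.affinity_sd, spec.probes_per_transcript)
        for tp in spec.timepoints:
            truth_rows.append(
                {
                    "transcript_id": tid,
                    "timepoint": tp,
                    "planted_fold": float(spec.planted_fold_changes.get((tid, tp), 1.0)),
                }
            )
        for p, a in enumerate(affin):
            rows.append({"probe_id": f"{tid}_p{p + 1:02d}", "transcript_id": tid, "_affinity": base * a})
    probes = pd.DataFrame(rows)
    scales = rng.lognormal(0.0, spec.array_scale_sd, len(design))
    tid_index = probes["transcript_id"].to_numpy()
    base_affinity = probes["_affinity"].to_numpy()
    fold_lookup = {
        (t["transcript_id"], t["timepoint"]): t["planted_fold"] for t in truth_rows
    }
    n_probes = len(probes)
    for row, scale in zip(design.to_dict(orient="records"), scales):
        fold = np.ones(n_probes)
        if row["condition"] == "test":
            fold = np.array([fold_lookup[(t, row["timepoint"])] for t in tid_index])
        noise = rng.lognormal(0.0, spec.probe_noise_sd, n_probes)
        values = base_affinity * fold * scale * noise
        if spec.outlier_probe_rate > 0:
            hit = rng.random(n_probes) < spec.outlier_probe_rate
            direction = rng.choice([spec.outlier_factor, 1.0 / spec.outlier_factor], size=n_probes)
            values = np.where(hit, values * direction, values)
        probes[row["array"]] = values
    probes = probes.drop(columns="_affinity")
    truth = pd.DataFrame(truth_rows)
    return probes, design, truth


def make_qpcr(
    ddct_values: dict,
    replicates: int = 4,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    reference_ct: float = 20.0,
    target_control_ct: float = 24.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct tables with planted ddCt per sample.

    ``ddct_values`` maps sample name -> true ddCt (positive = lower
    expression in the test condition).  ``replicates`` are technical
    replicates per (gene, condition); measurement noise is Gaussian on the
    Ct scale.  Returns ``(ct_table, truth)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    rows = []
    truth_rows = []
    for sample, ddct in ddct_values.items():
        truth_rows.append(
            {"sample": sample, "ddct": ddct, "relative_expression": 2.0 ** -ddct}
        )
        means = {
            ("reference", "control"): reference_ct,
            ("reference", "test"): reference_ct,
            ("target", "control"): target_control_ct,
            ("target", "test"): target_control_ct + ddct,
        }
        for (gene, condition), ct0 in means.items():
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct": ct0 + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
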