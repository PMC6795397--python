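"""End-to-end orchestration: video → trace → metrics → group statistics.

Every run writes its outputs together with a manifest echoing all
parameters and seeds, so results are reconstructible (and bit-identical on
rerun) from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .beats import BeatMetrics, compute_metrics, detect_beats
from .contractility import contractility_trace
from .piv import FrameStack, PivParams, displacement_series, select_reference_frame
from .qpcr import CqTable, fold_change_ddct, normalize_dct, unpaired_t_test

__all__ = ["RunConfig", "run_contractility", "run_group_comparison", "run_expression_report"]

METRIC_COLUMNS = ("D_peak", "D_mean", "T_cycle", "T_contract")


@dataclass
class RunConfig:
    """Configuration of one contractility run.

    Exactly one input source: ``input_path`` (a multi-page TIFF recorded at
    ``frame_rate``) or ``motion`` (a MotionSpec to synthesize).  The
    reference-selection pass may use its own, typically coarser, PIV
    parameters (``ref_params``): the speed minimum is insensitive to grid
    density and a sparse grid halves the runtime.
    """

    input_path: str | None = None
    frame_rate: float = 20.0
    motion: synthetic.MotionSpec | None = None
    noise_sigma: float = 0.01
    piv: PivParams = field(default_factory=PivParams)
    ref_params: PivParams | None = None
    convention: str = "absolute"
    min_prominence: float = 0.3
    min_separation: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.motion is None):
            raise ValueError("exactly one of input_path or motion must be set")
        if self.ref_params is None:
            self.ref_params = dataclasses.replace(self.piv, overlap=0)

    def to_manifest(self) -> dict:
        manifest = {
            "input_path": self.input_path,
            "frame_rate": self.frame_rate,
            "motion": dataclasses.asdict(self.motion) if self.motion else None,
            "noise_sigma": self.noise_sigma,
            "piv": dataclasses.asdict(self.piv),
            "ref_params": dataclasses.asdict(self.ref_params),
            "convention": self.convention,
            "min_prominence": self.min_prominence,
            "min_separation": self.min_separation,
            "seed": self.seed,
        }
        return manifest


def _load_stack(config: RunConfig) -> FrameStack:
    if config.input_path is not None:
        path = Path(config.input_path)
        if not path.exists():
            raise FileNotFoundError(f"input stack not found: {path}")
        return FrameStack.from_tiff(path, frame_rate=config.frame_rate)
    spec = config.motion
    # independent child streams for texture and sensor noise
    tex_seed, noise_seed = np.random.SeedSequence(config.seed).generate_state(2) >> 1
    texture = synthetic.make_speckle_texture(spec.width, spec.height, seed=int(tex_seed))
    return synthetic.render_beating_video(
        texture, spec, noise_sigma=config.noise_sigma, seed=int(noise_seed)
    )


def run_contractility(config: RunConfig, output_dir: str | Path) -> BeatMetrics:
    """Run the full pipeline and write trace, metrics, and manifest.

    Outputs in ``output_dir``: ``trace.csv`` (t, D, n_valid),
    ``metrics.json`` / ``metrics.csv``, and ``manifest.json``.  Reruns with
    an identical config produce bit-identical files.
    """
    stack = _load_stack(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref_index = select_reference_frame(stack, config.ref_params)
    fields = displacement_series(stack, ref_index, config.piv)
    trace = contractility_trace(fields, config.convention)
    peaks = detect_beats(trace, config.min_prominence, config.min_separation)
    metrics = compute_metrics(trace, peaks)
    trace.to_csv(out / "trace.csv")
    metrics.to_json(out / "metrics.json")
    metrics.to_csv(out / "metrics.csv")
    manifest = config.to_manifest()
    manifest["reference_frame"] = ref_index
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return metrics


def run_group_comparison(
    group_a_files: list[str | Path],
    group_b_files: list[str | Path],
    tails: int = 2,
    variance: str = "pooled",
    label_a: str = "control",
    label_b: str = "treated",
) -> pd.DataFrame:
    """Compare per-recording beat metrics between two groups.

    Each file is a ``metrics.json`` written by :func:`run_contractility`.
    Returns one row per metric: group means, SEM, n, percent difference of
    group B relative to group A, t, df, and p.
    """
    for label, files in ((label_a, group_a_files), (label_b, group_b_files)):
        if len(files) < 2:
            raise ValueError(f"group {label!r} needs >= 2 recordings, got {len(files)}")
    metrics_a = [BeatMetrics.from_json(f) for f in group_a_files]
    metrics_b = [BeatMetrics.from_json(f) for f in group_b_files]
    rows = []
    for name in METRIC_COLUMNS:
        vals_a = [m.to_dict()[name] for m in metrics_a]
        vals_b = [m.to_dict()[name] for m in metrics_b]
        if any(v is None for v in vals_a + vals_b):
            raise ValueError(f"metric {name} undefined in at least one recording")
        cmp = unpaired_t_test(vals_a, vals_b, tails=tails, variance=variance)
        rows.append(
            {
                "metric": name,
                f"mean_{label_a}": cmp.mean_a,
                f"sem_{label_a}": cmp.sem_a,
                f"n_{label_a}": cmp.n_a,
                f"mean_{label_b}": cmp.mean_b,
                f"sem_{label_b}": cmp.sem_b,
                f"n_{label_b}": cmp.n_b,
                "percent_difference": cmp.statistic,
                "t": cmp.t,
                "df": cmp.df,
                "p": cmp.p,
                "tails": cmp.tails,
            }
        )
    return pd.DataFrame(rows)


def run_expression_report(
    table: CqTable,
    reference_group: str,
    tails: int = 2,
    variance: str = "pooled",
) -> pd.DataFrame:
    """Per-group 2^-ΔΔCt fold changes relative to a reference group.

    Per-sample ΔCt values are formed by endogenous-control normalization;
    each non-reference group is compared with the reference by fold change
    and, where both groups have n ≥ 2, an unpaired t-test on ΔCt.
    """
    dct = normalize_dct(table)
    groups = list(dict.fromkeys(dct["group"]))
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in table")
    ref = dct.loc[dct["group"] == reference_group, "dct"].to_numpy()
    rows = []
    for group in groups:
        if group == reference_group:
            continue
        treated = dct.loc[dct["group"] == group, "dct"].to_numpy()
        fold = fold_change_ddct(treated, ref)
        row = {
            "comparison": f"{group} vs {reference_group}",
            "mean_dct_reference": float(ref.mean()),
            "mean_dct_group": float(treated.mean()),
            "fold_change": fold,
            "percent_change": 100.0 * (fold - 1.0),
            "t": np.nan,
            "df": np.nan,
            "p": np.nan,
            "tails": tails,
        }
        if ref.size >= 2 and treated.size >= 2 and (np.std(ref) > 0 or np.std(treated) > 0):
            cmp = unpaired_t_test(ref, treated, tails=tails, variance=variance,
                                  statistic_kind="fold")
            row.update({"t": cmp.t, "df": cmp.df, "p": cmp.p})
        rows.append(row)
    if not rows:
        raise ValueError("table contains no non-reference group to compare")
    return pd.DataFrame(rows)
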