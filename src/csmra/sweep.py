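"""Regularization-weight grid sweep: reconstruct, score, rank, report.

The default grids are the ten log-spaced weights used for both the
wavelet-L1 weight alpha and the TV weight beta,

    {3.2e-3, 1.0e-3, 3.2e-4, 1.0e-4, 3.2e-5, 1.0e-5, 3.2e-6, 1.0e-6,
     3.2e-7, 1.0e-7}

so a full sweep performs exactly 100 reconstructions.  Cells are evaluated
in a fixed deterministic order (alphas outer, betas inner, each as given);
cells are independent, so any execution order must produce identical output.
An optional observer-score grid (integers 1-5 per cell, e.g. transcribed
radiologist consensus scores) can be attached for rank-concordance analysis;
scores are never fabricated by the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import InvalidArgumentError
from .metrics import METRIC_DIRECTIONS, SSIMConfig, evaluate_all, mip, slice_nmse
from .phantom import MaskSet, Volume
from .recon import ReconProblem, fcsa_reconstruct
from .sift import detect_keypoints

#: the printed ten-value weight grid (descending)
DEFAULT_GRID = [3.2e-3, 1.0e-3, 3.2e-4, 1.0e-4, 3.2e-5, 1.0e-5, 3.2e-6, 1.0e-6, 3.2e-7, 1.0e-7]
ALPHA_GRID = list(DEFAULT_GRID)
BETA_GRID = list(DEFAULT_GRID)


@dataclass
class SweepGrid:
    """Per-(alpha, beta) metric records, plus optional observer scores."""

    alphas: list
    betas: list
    records: dict = field(default_factory=dict)  # (alpha, beta) -> {metric: value}
    scores: dict | None = None  # (alpha, beta) -> int in 1..5

    def validate(self):
        expect = {(a, b) for a in self.alphas for b in self.betas}
        if set(self.records) != expect:
            raise InvalidArgumentError(
                f"grid has {len(self.records)} records, expected {len(expect)}"
            )
        keys = None
        for rec in self.records.values():
            if keys is None:
                keys = set(rec)
            elif set(rec) != keys:
                raise InvalidArgumentError("records carry inconsistent metric sets")
        return self

    @property
    def metrics(self):
        any_rec = next(iter(self.records.values()))
        return sorted(any_rec)

    def __len__(self):
        return len(self.records)


def run_sweep(
    prob_template: ReconProblem,
    alphas,
    betas,
    ref: Volume,
    masks: MaskSet,
    ssim_cfg: SSIMConfig | None = None,
) -> SweepGrid:
    """One FCSA reconstruction + full metric evaluation per (alpha, beta).

    The reference MIP keypoints are detected once and reused for every cell
    (the reference does not change across the sweep).
    """
    alphas = [float(a) for a in alphas]
    betas = [float(b) for b in betas]
    if not alphas or not betas:
        raise InvalidArgumentError("alpha and beta grids must be non-empty")
    cfg = ssim_cfg or SSIMConfig()
    bmip = mip(ref, mask=masks.brain).data
    bref = bmip / float(bmip.max())
    ref_kps = detect_keypoints(bref)
    grid = SweepGrid(alphas=alphas, betas=betas)
    for a in alphas:
        for b in betas:
            prob = ReconProblem(
                prob_template.y,
                prob_template.mask,
                prob_template.coils,
                replace(prob_template.params, alpha=a, beta=b),
            )
            try:
                res = fcsa_reconstruct(prob)
            except Exception as exc:
                raise RuntimeError(
                    f"reconstruction failed at (alpha, beta) = ({a:g}, {b:g}): {exc}"
                ) from exc
            rec_mag = np.abs(res.image.data)
            vals = evaluate_all(ref, rec_mag, masks, ssim_cfg=cfg, ref_keypoints=ref_kps)
            vals["objective_first"] = res.objective_trace[0]
            vals["objective_last"] = res.objective_trace[-1]
            grid.records[(a, b)] = vals
    return grid.validate()


def top_k(grid: SweepGrid, metric: str, k: int = 10, direction: str | None = None):
    """Ranked list of (alpha, beta, value), best first.

    ``direction`` is ``lower_better`` or ``higher_better``; if omitted it is
    looked up in :data:`csmra.metrics.METRIC_DIRECTIONS`.  Ties are broken
    by (alpha, beta) in descending lexicographic order, so rankings are
    reproducible.
    """
    if not grid.records or metric not in next(iter(grid.records.values())):
        raise InvalidArgumentError(f"metric {metric!r} not present in grid records")
    if direction is None:
        direction = METRIC_DIRECTIONS.get(metric)
        if direction is None:
            raise InvalidArgumentError(f"no ranking direction known for {metric!r}")
    if direction not in ("lower_better", "higher_better"):
        raise InvalidArgumentError(f"bad direction {direction!r}")
    sign = 1.0 if direction == "lower_better" else -1.0
    items = [(a, b, grid.records[(a, b)][metric]) for a, b in grid.records]
    items.sort(key=lambda t: (sign * t[2], -t[0], -t[1]))
    return items[: min(k, len(items))]


def rank_concordance(grid: SweepGrid, metric: str, direction: str | None = None) -> float:
    """Spearman rank correlation between a metric and observer scores.

    The metric is oriented so that higher = better before correlating, so a
    perfectly concordant metric gives +1 regardless of its natural
    direction.
    """
    if grid.scores is None:
        raise InvalidArgumentError("grid has no observer scores")
    if direction is None:
        direction = METRIC_DIRECTIONS.get(metric)
        if direction is None:
            raise InvalidArgumentError(f"no ranking direction known for {metric!r}")
    cells = sorted(grid.records)
    vals = np.array([grid.records[c][metric] for c in cells], dtype=float)
    if direction == "lower_better":
        vals = -vals
    scores = np.array([grid.scores[c] for c in cells], dtype=float)
    rho = spearmanr(vals, scores).statistic
    return float(rho)


def grid_to_frame(grid: SweepGrid) -> pd.DataFrame:
    rows = []
    for a in grid.alphas:
        for b in grid.betas:
            row = {"alpha": a, "beta": b}
            row.update(grid.records[(a, b)])
            if grid.scores is not None:
                row["score"] = grid.scores[(a, b)]
            rows.append(row)
    return pd.DataFrame(rows)


def grid_from_frame(df: pd.DataFrame) -> SweepGrid:
    alphas = list(dict.fromkeys(df["alpha"]))
    betas = list(dict.fromkeys(df["beta"]))
    metric_cols = [c for c in df.columns if c not in ("alpha", "beta", "score")]
    records = {}
    scores = {} if "score" in df.columns else None
    for _, row in df.iterrows():
        key = (float(row["alpha"]), float(row["beta"]))
        records[key] = {c: float(row[c]) for c in metric_cols}
        if scores is not None:
            scores[key] = int(row["score"])
    return SweepGrid(alphas=alphas, betas=betas, records=records, scores=scores).validate()


def load_scores_csv(path) -> dict:
    """Observer scores from a CSV with columns alpha, beta, score."""
    df = pd.read_csv(path)
    return {(float(r["alpha"]), float(r["beta"])): int(r["score"]) for _, r in df.iterrows()}


def render_reports(grid: SweepGrid, outdir, top: int = 10) -> list:
    """Write per-metric color maps, the full metrics CSV and top-k tables.

    Color maps are oriented with alpha on the vertical axis increasing
    downward (smallest alpha at the top) and beta on the horizontal axis
    increasing to the right.  Returns the list of written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    df = grid_to_frame(grid)
    csv_path = outdir / "metrics.csv"
    df.to_csv(csv_path, index=False)
    written.append(csv_path)

    a_sorted = sorted(grid.alphas)  # smallest at top
    b_sorted = sorted(grid.betas)  # smallest at left
    for metric in grid.metrics:
        mat = np.array(
            [[grid.records[(a, b)][metric] for b in b_sorted] for a in a_sorted]
        )
        fig, ax = plt.subplots(figsize=(5, 4.5))
        finite = np.isfinite(mat)
        im = ax.imshow(
            np.where(finite, mat, np.nan),
            cmap="jet",
            aspect="auto",
        )
        ax.set_xticks(range(len(b_sorted)), [f"{b:.1e}" for b in b_sorted], rotation=90, fontsize=6)
        ax.set_yticks(range(len(a_sorted)), [f"{a:.1e}" for a in a_sorted], fontsize=6)
        ax.set_xlabel("beta (TV weight)")
        ax.set_ylabel("alpha (wavelet weight)")
        ax.set_title(metric)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        png = outdir / f"{metric}.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        written.append(png)

        if metric in METRIC_DIRECTIONS:
            ranked = top_k(grid, metric, k=top)
            tdf = pd.DataFrame(ranked, columns=["alpha", "beta", metric])
            tpath = outdir / f"top{top}_{metric}.csv"
            tdf.to_csv(tpath, index=False)
            written.append(tpath)

    if grid.scores is not None:
        conc = {
            m: rank_concordance(grid, m) for m in grid.metrics if m in METRIC_DIRECTIONS
        }
        cpath = outdir / "rank_concordance.json"
        cpath.write_text(json.dumps(conc, indent=2))
        written.append(cpath)
    return written
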