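"""Robustness of predictions under observation subsampling.

Two complementary analyses quantify how predictions depend on the amount
of experimental data:

* **precision** — for each sub-run, the score ``s = m / t`` where t is the
  number of sign predictions whose node maps to a measured gene and m the
  number matching the fold-change direction (all discretization thresholds
  removed: any positive fold-change agrees with a + prediction, any
  negative with a -);
* **stability** — each node predicted in the full-observation reference
  run is classified per sub-run as *good* (same sign), *bad* (different
  sign) or *missing* (not predicted).

The default plan samples 10%..95% of the observations in steps of 5
(stratified by sign, round-half-up), 100 replicates per fraction: 1800
experiments.  Each experiment's RNG seed derives from (plan seed, fraction,
replicate), so results are independent of execution order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .consistency import PredictionMap, predict
from .model import NodeKind, ObservationSet, Sign, SignedInteractionGraph, node_kind_of

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingPlan",
    "StabilityCounts",
    "PrecisionResult",
    "sample_observations",
    "precision_score",
    "stability_classify",
    "run_sampling_study",
    "summarize",
    "plot_precision",
    "plot_stability",
    "PrecisionUndefinedError",
]


class PrecisionUndefinedError(ValueError):
    """No prediction maps to a measured gene (t = 0)."""


@dataclass(frozen=True)
class SamplingPlan:
    """Subsampling design: fractions (percent), replicates per fraction, seed."""

    fractions: tuple[int, ...] = tuple(range(10, 100, 5))
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < f < 100 for f in self.fractions):
            raise ValueError("fractions must lie strictly between 0 and 100")
        if list(self.fractions) != sorted(set(self.fractions)):
            raise ValueError("fractions must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")

    @property
    def n_experiments(self) -> int:
        return len(self.fractions) * self.replicates

    def iter_experiments(self) -> Iterator[tuple[int, int, list[int]]]:
        """(fraction, replicate, derived seed-sequence) per experiment."""
        for fraction in self.fractions:
            for replicate in range(self.replicates):
                yield fraction, replicate, [self.seed, fraction, replicate]


@dataclass(frozen=True)
class StabilityCounts:
    good: int
    bad: int
    missing: int
    fraction: int | None = None
    replicate: int | None = None

    @property
    def total(self) -> int:
        return self.good + self.bad + self.missing


@dataclass(frozen=True)
class PrecisionResult:
    m: int
    t: int
    n_zero: int = 0  # 0-sign predictions, reported separately

    @property
    def score(self) -> float:
        return self.m / self.t


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def sample_observations(
    observations: ObservationSet,
    fraction: float,
    seed: int | list[int],
) -> ObservationSet:
    """Stratified subsample: the same fraction of each sign stratum.

    Stratum sizes use round-half-up; a stratum rounding to zero at very low
    fractions is allowed (and logged).  Deterministic under ``seed``.
    """
    if not 0 < fraction < 100:
        raise ValueError("fraction must lie strictly between 0 and 100")
    rng = np.random.default_rng(seed)
    picked: dict[str, Sign] = {}
    for sign in (Sign.PLUS, Sign.MINUS, Sign.ZERO):
        stratum = observations.by_sign(sign)
        if not stratum:
            continue
        k = _round_half_up(fraction / 100 * len(stratum))
        if k == 0:
            logger.debug("stratum %s empty at %s%% (size %d)", sign, fraction, len(stratum))
            continue
        for node in rng.choice(stratum, size=k, replace=False):
            picked[str(node)] = sign
    return ObservationSet(picked)


def node_symbol(node_id: str) -> str | None:
    """Gene symbol a prediction node maps to; None for complexes."""
    if node_kind_of(node_id) is NodeKind.COMPLEX:
        return None
    return node_id.removesuffix("_gen").removesuffix("_prot")


def precision_score(
    predictions: PredictionMap, foldchanges: Mapping[str, float]
) -> PrecisionResult:
    """s = m/t against raw fold-change directions (thresholds removed)."""
    m = t = n_zero = 0
    for node, sign in predictions.predictions.items():
        symbol = node_symbol(node)
        if symbol is None or symbol not in foldchanges:
            continue
        fc = foldchanges[symbol]
        if sign is Sign.ZERO:
            # a 0 prediction would only match a fold-change of exactly 0;
            # counted apart so they cannot silently deflate the score
            n_zero += 1
            continue
        t += 1
        if (sign is Sign.PLUS and fc > 0) or (sign is Sign.MINUS and fc < 0):
            m += 1
    if t == 0:
        raise PrecisionUndefinedError("no sign prediction maps to a measured gene")
    return PrecisionResult(m=m, t=t, n_zero=n_zero)


def stability_classify(
    reference: PredictionMap,
    sub: PredictionMap,
    fraction: int | None = None,
    replicate: int | None = None,
) -> StabilityCounts:
    """Classify every reference-predicted node as good / bad / missing."""
    if not reference.predictions:
        raise ValueError("reference prediction map is empty")
    good = bad = missing = 0
    for node, sign in reference.predictions.items():
        sub_sign = sub.predictions.get(node)
        if sub_sign is None:
            missing += 1
        elif sub_sign is sign:
            good += 1
        else:
            bad += 1
    return StabilityCounts(good, bad, missing, fraction=fraction, replicate=replicate)


def run_sampling_study(
    graph: SignedInteractionGraph,
    observations: ObservationSet,
    foldchanges: Mapping[str, float],
    plan: SamplingPlan,
    max_k: int = 3,
) -> pd.DataFrame:
    """Run the full subsampling study; one tidy row per experiment.

    Repairs are recomputed per subset (a subset may resolve a conflict that
    the full set exhibits).  The reference row (fraction 100) is appended
    last.  Columns: fraction, replicate, t, m, s, good, bad, missing,
    n_predictions plus both stability normalizations.
    """
    reference, ref_report = predict(graph, observations, max_k=max_k)
    n_ref = len(reference.predictions)
    if n_ref == 0:
        raise ValueError("reference run produced no predictions; nothing to track")
    try:
        ref_precision = precision_score(reference, foldchanges)
        ref_m, ref_t, ref_s = ref_precision.m, ref_precision.t, ref_precision.score
    except PrecisionUndefinedError:
        ref_m, ref_t, ref_s = 0, 0, float("nan")
    logger.info(
        "reference run: %d predictions, MCoS k=%d, precision %.3f",
        n_ref,
        ref_report.k,
        ref_s,
    )
    rows = []
    for fraction, replicate, seed in plan.iter_experiments():
        sub_obs = sample_observations(observations, fraction, seed)
        sub_pred, _ = predict(graph, sub_obs, max_k=max_k)
        try:
            prec = precision_score(sub_pred, foldchanges)
            m, t, s = prec.m, prec.t, prec.score
        except PrecisionUndefinedError:
            m, t, s = 0, 0, float("nan")
        stab = stability_classify(reference, sub_pred, fraction, replicate)
        n_sub = len(sub_pred.predictions)
        rows.append(
            {
                "fraction": fraction,
                "replicate": replicate,
                "n_observations": len(sub_obs),
                "n_predictions": n_sub,
                "t": t,
                "m": m,
                "s": s,
                "good": stab.good,
                "bad": stab.bad,
                "missing": stab.missing,
                "good_frac_sub": stab.good / n_sub if n_sub else float("nan"),
                "bad_frac_sub": stab.bad / n_sub if n_sub else float("nan"),
                "missing_frac_sub": stab.missing / n_sub if n_sub else float("nan"),
                "good_frac_ref": stab.good / n_ref,
                "bad_frac_ref": stab.bad / n_ref,
                "missing_frac_ref": stab.missing / n_ref,
            }
        )
    rows.append(
        {
            "fraction": 100,
            "replicate": 0,
            "n_observations": len(observations),
            "n_predictions": n_ref,
            "t": ref_t,
            "m": ref_m,
            "s": ref_s,
            "good": n_ref,
            "bad": 0,
            "missing": 0,
            "good_frac_sub": 1.0,
            "bad_frac_sub": 0.0,
            "missing_frac_sub": 0.0,
            "good_frac_ref": 1.0,
            "bad_frac_ref": 0.0,
            "missing_frac_ref": 0.0,
        }
    )
    return pd.DataFrame(rows)


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Per-fraction min / median / mean / max of precision and stability."""
    cols = ["s", "good_frac_sub", "bad_frac_sub", "missing_frac_sub"]
    return df.groupby("fraction")[cols].agg(["min", "median", "mean", "max"])


def plot_precision(df: pd.DataFrame, path: str | Path) -> None:
    """Boxplots of the precision score per sampling fraction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fractions = sorted(df["fraction"].unique())
    data = [df.loc[df["fraction"] == f, "s"].dropna().to_numpy() for f in fractions]
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.boxplot(data, tick_labels=[str(f) for f in fractions])
    ax.set_xlabel("sampled observations (%)")
    ax.set_ylabel("precision score s = m/t")
    ax.set_title("Prediction precision under observation subsampling")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_stability(
    df: pd.DataFrame, path: str | Path, normalize: str = "sub"
) -> None:
    """Min/median/mean/max curves for good / bad / missing per fraction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    suffix = {"sub": "_frac_sub", "reference": "_frac_ref"}[normalize]
    sub = df[df["fraction"] < 100]
    fig, ax = plt.subplots(figsize=(9, 4.5))
    colors = {"good": "tab:green", "bad": "tab:red", "missing": "tab:blue"}
    for cat, color in colors.items():
        grouped = sub.groupby("fraction")[f"{cat}{suffix}"]
        for stat, style in (("max", ":"), ("median", "--"), ("mean", "-"), ("min", ":")):
            series = grouped.agg(stat)
            ax.plot(
                series.index,
                series.to_numpy(),
                style,
                color=color,
                label=f"{cat} ({stat})" if stat == "mean" else None,
                alpha=0.8 if stat == "mean" else 0.45,
            )
    ax.set_xlabel("sampled observations (%)")
    ax.set_ylabel(f"fraction of predictions (normalized to {normalize}-run count)")
    ax.set_title("Stability of predictions versus the full-observation run")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_report(
    df: pd.DataFrame, outdir: str | Path, normalize: str = "sub"
) -> dict[str, str]:
    """Write experiments.csv, summary.json and both plots; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "experiments": str(outdir / "experiments.csv"),
        "summary": str(outdir / "summary.json"),
        "precision_plot": str(outdir / "precision.png"),
        "stability_plot": str(outdir / "stability.png"),
    }
    df.to_csv(paths["experiments"], index=False)
    summary = summarize(df)
    summary.columns = ["_".join(c) for c in summary.columns]
    Path(paths["summary"]).write_text(
        json.dumps(json.loads(summary.to_json(orient="index")), indent=2)
    )
    plot_precision(df, paths["precision_plot"])
    plot_stability(df, paths["stability_plot"], normalize=normalize)
    return paths
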