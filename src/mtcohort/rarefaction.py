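"""Sample-size-standardised diversity comparison by resampling.

Groups of unequal sample size cannot be compared directly on statistics such
as the number of haplotypes.  Here every statistic is re-estimated on
``n_resamples`` draws of ``k`` sequences **with replacement** from a group,
for ``k`` running over a grid, giving a mean +/- standard-error curve per
statistic and group.  Two cohorts are then compared per ``k`` by flagging the
sample sizes at which their mean +/- SE intervals no longer overlap.

Statistics whose value is undefined on a particular draw (``D`` with no
segregating site, ``Y`` with only singletons) are dropped from that draw's
average and counted, never imputed.

The resampling is fully vectorised: per group we precompute the one-hot
allele indicators of the segregating usable columns and the haplotype
membership matrix, so a resample reduces to integer gathers and sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, AlignmentError, collapse_haplotypes
from .popgen import achaz_constants, harmonic, tajima_constants

__all__ = ["RarefactionCurve", "rarefaction_curves", "compare_curves", "STATISTICS"]

STATISTICS = ("H", "Hd", "pi", "thetaW", "D", "Y")

#: statistics requiring a larger minimum draw for their variance terms
_K_MIN = {"H": 2, "Hd": 2, "pi": 2, "thetaW": 2, "D": 3, "Y": 4}


@dataclass
class RarefactionCurve:
    """Mean/SE of one statistic across resampled sample sizes ``k``."""

    statistic: str
    group: str
    k: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_valid: np.ndarray
    n_resamples: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stat": self.statistic,
                "group": self.group,
                "k": self.k,
                "mean": self.mean,
                "se": self.se,
                "n_valid": self.n_valid,
            }
        )


class _GroupData:
    """Precomputed per-group arrays for fast with-replacement resampling."""

    def __init__(self, aln: Alignment):
        self.n = aln.n
        usable = aln.usable_columns()
        self.L = int(usable.sum())
        if self.L == 0:
            raise AlignmentError("no usable columns under complete deletion")
        sub = aln.matrix[:, usable]
        variable = (sub != sub[0]).any(axis=0)
        var_cols = sub[:, variable]
        # (n, v, 4) one-hot of A/C/G/T per variable usable column
        codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        self.onehot = (var_cols[:, :, None] == codes[None, None, :])
        haps = collapse_haplotypes(aln)
        hap_idx = pd.Categorical(
            haps.assignments.values, categories=haps.labels
        ).codes
        self.hap_onehot = np.eye(haps.n_haplotypes, dtype=np.int32)[hap_idx]


def _resample_stats(gd: _GroupData, k: int, idx: np.ndarray, stats) -> dict[str, np.ndarray]:
    """Statistic values for a block of resamples. ``idx``: (R, k) row draws."""
    R = idx.shape[0]
    out: dict[str, np.ndarray] = {}

    need_counts = any(s in stats for s in ("pi", "thetaW", "D", "Y"))
    if need_counts:
        # (R, v, 4) allele counts among the k drawn sequences
        counts = gd.onehot[idx].sum(axis=1)
        n_alleles = (counts > 0).sum(axis=2)
        seg = n_alleles >= 2
        S = seg.sum(axis=1).astype(float)
        pair = np.where(seg, (k * k - (counts.astype(np.int64) ** 2).sum(axis=2)) / 2.0, 0.0)
        pairs = k * (k - 1) / 2.0
        pi_locus = pair.sum(axis=1) / pairs
        if "pi" in stats:
            out["pi"] = pi_locus / gd.L
        if "thetaW" in stats:
            out["thetaW"] = S / (harmonic(k) * gd.L)
        if "D" in stats:
            a1, e1, e2 = tajima_constants(k)
            var = e1 * S + e2 * S * (S - 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                D = (pi_locus - S / a1) / np.sqrt(var)
            D[(S < 1) | (var <= 0)] = np.nan
            out["D"] = D
        if "Y" in stats:
            pi_denom, w_denom, alpha, beta, c2 = achaz_constants(k)
            informative = (counts >= 2).sum(axis=2) >= 2
            ns = seg & informative
            S_ns = ns.sum(axis=1).astype(float)
            pair_ns = np.where(ns, pair, 0.0).sum(axis=1)
            theta_pi = pair_ns / pi_denom
            theta_w = S_ns / w_denom
            theta_sq = S_ns * (S_ns - 1.0) / (w_denom**2 + c2)
            var = alpha * theta_w + beta * theta_sq
            with np.errstate(divide="ignore", invalid="ignore"):
                Y = (theta_pi - theta_w) / np.sqrt(var)
            Y[(S_ns < 1) | (var <= 0)] = np.nan
            out["Y"] = Y

    if "H" in stats or "Hd" in stats:
        hcounts = gd.hap_onehot[idx].sum(axis=1)  # (R, n_hap)
        if "H" in stats:
            out["H"] = (hcounts > 0).sum(axis=1).astype(float)
        if "Hd" in stats:
            p = hcounts / float(k)
            out["Hd"] = k / (k - 1.0) * (1.0 - (p**2).sum(axis=1))
    return out


def rarefaction_curves(
    aln: Alignment,
    group_name: str = "",
    statistics=STATISTICS,
    k_min: int | None = None,
    k_max: int | None = None,
    n_resamples: int = 5000,
    seed: int | None = None,
    block_size: int = 1000,
) -> dict[str, RarefactionCurve]:
    """Rarefaction curves for one group (the alignment's sequences).

    ``k`` runs from ``k_min`` (default 2, or 3/4 where the statistic's
    variance terms require it) to ``k_max`` (default ``min(n, 50)``).  All
    requested statistics are computed from the same draws; each draw is ``k``
    sequences sampled with replacement.
    """
    stats = tuple(statistics)
    unknown = [s for s in stats if s not in STATISTICS]
    if unknown:
        raise ValueError(f"unknown statistics: {unknown}; choose from {STATISTICS}")
    gd = _GroupData(aln)
    lo = 2 if k_min is None else k_min
    hi = min(gd.n, 50) if k_max is None else k_max
    if hi < lo:
        raise AlignmentError(f"k_max={hi} below k_min={lo}")
    rng = np.random.default_rng(seed)

    ks = np.arange(lo, hi + 1)
    acc = {s: {"mean": [], "se": [], "valid": [], "k": []} for s in stats}
    for k in ks:
        stats_k = tuple(s for s in stats if k >= _K_MIN[s])
        values = {s: [] for s in stats}
        remaining = n_resamples
        while remaining > 0:
            R = min(block_size, remaining)
            idx = rng.integers(0, gd.n, size=(R, k))
            block = _resample_stats(gd, int(k), idx, stats_k)
            for s in stats:
                if s in block:
                    values[s].append(block[s])
            remaining -= R
        for s in stats:
            if k < _K_MIN[s]:
                continue
            v = np.concatenate(values[s])
            ok = np.isfinite(v)
            nv = int(ok.sum())
            acc[s]["k"].append(k)
            acc[s]["valid"].append(nv)
            if nv == 0:
                acc[s]["mean"].append(np.nan)
                acc[s]["se"].append(np.nan)
            else:
                acc[s]["mean"].append(float(v[ok].mean()))
                acc[s]["se"].append(
                    float(v[ok].std(ddof=1) / np.sqrt(nv)) if nv > 1 else 0.0
                )
    return {
        s: RarefactionCurve(
            statistic=s,
            group=group_name,
            k=np.array(acc[s]["k"]),
            mean=np.array(acc[s]["mean"]),
            se=np.array(acc[s]["se"]),
            n_valid=np.array(acc[s]["valid"]),
            n_resamples=n_resamples,
            seed=seed,
        )
        for s in stats
    }


def compare_curves(curve_a: RarefactionCurve, curve_b: RarefactionCurve) -> pd.DataFrame:
    """Per-k flags where the two mean +/- SE intervals are disjoint.

    ``direction`` is +1 where curve_a lies above curve_b, -1 below, 0 where
    the intervals overlap or either mean is missing.
    """
    if curve_a.k.shape != curve_b.k.shape or not np.array_equal(curve_a.k, curve_b.k):
        raise ValueError("curves must share the same k grid")
    lo_a, hi_a = curve_a.mean - curve_a.se, curve_a.mean + curve_a.se
    lo_b, hi_b = curve_b.mean - curve_b.se, curve_b.mean + curve_b.se
    defined = np.isfinite(curve_a.mean) & np.isfinite(curve_b.mean)
    above = defined & (lo_a > hi_b)
    below = defined & (hi_a < lo_b)
    return pd.DataFrame(
        {
            "k": curve_a.k,
            "mean_a": curve_a.mean,
            "se_a": curve_a.se,
            "mean_b": curve_b.mean,
            "se_b": curve_b.se,
            "nonoverlap": above | below,
            "direction": np.where(above, 1, np.where(below, -1, 0)),
        }
    )


def curves_to_frame(curves) -> pd.DataFrame:
    """Stack curves (possibly from several groups) into one long table."""
    frames = []
    for c in curves if not isinstance(curves, dict) else curves.values():
        frames.append(c.to_frame())
    return pd.concat(frames, ignore_index=True)
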