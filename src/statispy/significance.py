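"""Bootstrap-over-tables significance of observation contributions.

The compromise component space is held fixed at the full-data solution; each
bootstrap replicate draws K tables uniformly with replacement, recomputes the
table weights on the resampled congruence matrix and projects the resampled
compromise onto the fixed components:

    F* = S* M P Delta^-1 = sum_i alpha*_i F_idx(i)

(the per-table partial factor scores make this a cheap weighted average).
The bootstrap ratio mean/sd over replicates behaves like a t statistic:
observations whose projections are stable across table resamples get large
|ratio| and are flagged at the chosen significance level. Refitting the
decomposition per replicate would misalign components across replicates
(rotation and sign indeterminacy), which is why the projection scheme is
used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import StatisResults

logger = logging.getLogger(__name__)

BASES = ("factor_scores", "contributions")

#: sd below this is treated as degenerate (all replicates identical)
DEGENERATE_SD = 1e-12


@dataclass
class BootstrapResult:
    """Per-observation, per-component bootstrap ratios and flags."""

    n_boot: int
    ratios: np.ndarray  # n x r, +-inf where sd degenerated
    mean_scores: np.ndarray
    sd_scores: np.ndarray
    significant: np.ndarray  # n x r booleans at alpha_level
    alpha_level: float
    basis: str
    row_ids: list[str]


def _flags(ratios: np.ndarray, mean: np.ndarray, sd: np.ndarray,
           alpha_level: float, basis: str) -> np.ndarray:
    degenerate = sd < DEGENERATE_SD
    if basis == "factor_scores":
        z = stats.norm.ppf(1 - alpha_level / 2)
        sig = np.abs(ratios) >= z
        sig[degenerate] = np.abs(mean[degenerate]) > DEGENERATE_SD
    else:  # contributions are non-negative: one-sided
        z = stats.norm.ppf(1 - alpha_level)
        sig = ratios >= z
        sig[degenerate] = mean[degenerate] > DEGENERATE_SD
    return sig


def bootstrap_tables(
    results: StatisResults,
    n_boot: int = 1000,
    seed: int | None = None,
    basis: str = "factor_scores",
    alpha_level: float = 0.01,
) -> BootstrapResult:
    """Bootstrap ratios from resampling the set of tables with replacement.

    Parameters
    ----------
    results : StatisResults
        A fitted full-data run; its component space stays fixed.
    n_boot : int
        Number of replicates (>= 50).
    seed : int
        Seed for the resampling RNG (mandatory for reproducibility).
    basis : {"factor_scores", "contributions"}
        Statistic the ratios are computed on: signed factor scores
        (two-sided flags) or non-negative row contributions (one-sided).
    alpha_level : float
        Significance level for the normal-quantile flag threshold.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    if basis not in BASES:
        raise ValueError(f"basis must be one of {BASES}")
    if seed is None:
        raise ValueError("a seed is required for a reproducible bootstrap")
    rng = np.random.default_rng(seed)

    K = len(results.table_ids)
    C = results.interstructure.C
    F_partial = np.stack(results.scores.F_partial)  # K x n x r
    dec = results.decomposition
    lam = dec.Delta**2
    m = dec.masses.masses

    n, r = results.scores.F.shape
    acc = np.empty((n_boot, n, r))
    for b in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, K, size=K)
            Cb = C[np.ix_(idx, idx)]
            if np.any(Cb != 0):
                break
            logger.warning("bootstrap replicate %d: all-zero resampled congruence; redrawn", b)
        else:  # pragma: no cover - requires pathological input
            raise ValueError("resampled congruence matrix is always zero")
        evals, evecs = np.linalg.eigh(Cb)
        u = evecs[:, -1]
        if u.sum() < 0:
            u = -u
        u = np.clip(u, 0.0, None)
        alpha = u / u.sum()
        Fb = np.tensordot(alpha, F_partial[idx], axes=(0, 0))  # n x r
        if basis == "factor_scores":
            acc[b] = Fb
        else:
            acc[b] = m[:, None] * Fb**2 / lam[None, :]

    mean = acc.mean(axis=0)
    sd = acc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = mean / sd
    degenerate = sd < DEGENERATE_SD
    ratios[degenerate] = np.where(
        np.abs(mean[degenerate]) > DEGENERATE_SD,
        np.sign(mean[degenerate]) * np.inf,
        0.0,
    )
    sig = _flags(ratios, mean, sd, alpha_level, basis)
    return BootstrapResult(
        n_boot=n_boot,
        ratios=ratios,
        mean_scores=mean,
        sd_scores=sd,
        significant=sig,
        alpha_level=alpha_level,
        basis=basis,
        row_ids=list(results.row_ids),
    )


def significant_genes(
    result: BootstrapResult,
    alpha_level: float = 0.01,
    union_components: tuple[int, ...] = (1, 2),
) -> dict[str, list[str]]:
    """Gene lists per component plus the union over selected components.

    Keys are ``"PC1"``, ``"PC2"``, ... and ``"union"`` (default over the
    first two components, mirroring the selection of genes significant on
    either of the leading components).
    """
    flags = _flags(result.ratios, result.mean_scores, result.sd_scores,
                   alpha_level, result.basis)
    r = flags.shape[1]
    out: dict[str, list[str]] = {}
    for b in range(r):
        out[f"PC{b + 1}"] = [g for g, f in zip(result.row_ids, flags[:, b]) if f]
    union_idx = [b - 1 for b in union_components if 1 <= b <= r]
    pooled = flags[:, union_idx].any(axis=1) if union_idx else np.zeros(len(result.row_ids), bool)
    out["union"] = [g for g, f in zip(result.row_ids, pooled) if f]
    return out
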