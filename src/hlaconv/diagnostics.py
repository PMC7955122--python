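"""Imputation diagnostics: LD-decay indices, sensitivity maps, uncertainty.

Three questions about a trained imputation model are answered here.  How
much of an allele's information is carried by nearby versus distant SNVs is
summarised by the AUC of the bilateral cumulative r2 curve (distance-
dependent LD decay) and by the maximum r2 within the nearest 100 SNVs, and
related to per-allele accuracy by frequency-adjusted linear regression.
Which input SNVs the network actually uses is estimated by SmoothGrad
(noise-averaged absolute input gradients).  How trustworthy an individual
imputed genotype is comes from Monte-Carlo dropout: the binary entropy of
the agreement between repeated stochastic predictions and the deterministic
best guess, compared by ROC against a dosage-probability score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import AlleleProbabilities, TrainedGroupModel, impute, mc_dropout_sample
from .panel import UNKNOWN, PhasedPanel

# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


@dataclass
class LDProfile:
    """Per-SNV r2 with one HLA allele, sorted by distance from the allele."""

    gene: str
    allele: str
    allele_pos: int
    table: pd.DataFrame  # columns: id, pos_bp, r2, monomorphic; distance-sorted
    window: str


def _indicator_r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ld_profile(
    panel: PhasedPanel,
    gene: str,
    allele: str,
    allele_pos: int,
    res: int = 4,
    window_idx: np.ndarray | None = None,
    max_rank: int | None = None,
) -> LDProfile:
    """r2 between the allele carrier-indicator and each SNV across panel
    haplotypes.  ``window_idx`` restricts to a model window
    ("model_window"); ``max_rank`` keeps the bilaterally nearest SNVs
    ("bilateral_rank" window).  Monomorphic SNVs get r2 = 0, flagged."""
    lab = panel.effective_labels(gene, res)
    ind = (lab == allele).astype(float)
    if ind.sum() < 2:
        raise ValueError(f"allele {gene}*{allele} present on <2 haplotypes")
    idx = np.arange(len(panel.variants)) if window_idx is None else np.asarray(window_idx)
    pos = panel.positions[idx]
    order = np.argsort(np.abs(pos - allele_pos), kind="stable")
    idx, pos = idx[order], pos[order]
    if max_rank is not None:
        idx, pos = idx[:max_rank], pos[:max_rank]
    rows = []
    for j, p in zip(idx, pos):
        snv = panel.haplotypes[:, j].astype(float)
        mono = snv.std() == 0.0
        rows.append((panel.variants[j].id, int(p), _indicator_r2(ind, snv), bool(mono)))
    window = "model_window" if window_idx is not None else (
        f"bilateral_rank_{max_rank}" if max_rank else "all"
    )
    return LDProfile(gene, allele, allele_pos, pd.DataFrame(
        rows, columns=["id", "pos_bp", "r2", "monomorphic"]), window)


def auc_ld_decay(profile: LDProfile | np.ndarray) -> float:
    """AUC of the normalised bilateral cumulative r2 curve.

    SNVs are ranked by increasing distance; the cumulative r2 curve is
    normalised to [0, 1] on both axes (x = rank / W, y = cumulative r2 /
    total r2) and integrated by the trapezoid rule from the origin.  A curve
    rising fastest near the allele (distance-dependent decay) is convex
    upward and scores above 0.5; r2 mass concentrated on the single nearest
    SNV approaches 1 - 1/(2W).  Total r2 of zero is undefined (NaN, warned).
    """
    r2 = profile if isinstance(profile, np.ndarray) else profile.table["r2"].to_numpy()
    total = r2.sum()
    if total <= 0.0:
        warnings.warn("total r2 is zero; LD-decay AUC undefined")
        return float("nan")
    W = len(r2)
    x = np.arange(W + 1) / W
    y = np.concatenate([[0.0], np.cumsum(r2) / total])
    return float(np.trapezoid(y, x))


def max_ld_within(profile: LDProfile, k: int = 100) -> float:
    """Maximum r2 over the k bilaterally nearest SNVs."""
    return float(profile.table["r2"].to_numpy()[:k].max())


def accuracy_vs_ld_regression(
    metric: np.ndarray, auc: np.ndarray, freq: np.ndarray
) -> pd.DataFrame:
    """OLS of a per-allele accuracy metric on (AUC, allele frequency) with an
    intercept; returns coefficients with standard errors."""
    y = np.asarray(metric, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(auc, float), np.asarray(freq, float)])
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    if len(y) < 3 or np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient or underdetermined regression design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof if dof > 0 else np.nan
    cov = s2 * np.linalg.inv(X.T @ X)
    return pd.DataFrame(
        {"coef": beta, "se": np.sqrt(np.diag(cov))},
        index=["intercept", "auc", "freq"],
    )


# ---------------------------------------------------------------------------
# SmoothGrad sensitivity maps
# ---------------------------------------------------------------------------


@dataclass
class SensitivityMap:
    gene: str
    allele: str
    values: np.ndarray  # per-SNV mean absolute gradient, >= 0
    n_noise: int
    noise_sd: float
    n_haplotypes: int


def smoothgrad(
    model: TrainedGroupModel,
    gene: str,
    allele: str,
    carrier_X: np.ndarray,
    n: int = 200,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SensitivityMap:
    """Noise-averaged absolute input gradient of one allele's pre-softmax
    score, averaged over carrier haplotypes.

    Gaussian noise is added to the continuous relaxation of the one-hot
    input; gradients are summed in magnitude over the two one-hot channels.
    ``noise_sd = 0`` degenerates to the plain absolute gradient.
    Deterministic given ``seed``.
    """
    carrier_X = np.asarray(carrier_X, dtype=float)
    if carrier_X.ndim == 2:
        carrier_X = carrier_X[None]
    if carrier_X.shape[0] == 0:
        raise ValueError(f"no carrier haplotypes for {gene}*{allele}")
    a_idx = model.alleles[gene].index(allele)
    rng = np.random.default_rng(seed)
    maps = []
    for hap in carrier_X:
        batch = np.tile(hap, (n, 1, 1))
        if noise_sd > 0:
            batch = batch + rng.normal(0.0, noise_sd, size=batch.shape)
        grad = model.net.input_gradient(batch, gene, a_idx)
        maps.append(np.abs(grad).sum(axis=1).mean(axis=0))  # sum channels, mean noise
    values = np.mean(maps, axis=0)
    return SensitivityMap(gene, allele, values, n, noise_sd, carrier_X.shape[0])


# ---------------------------------------------------------------------------
# MC-dropout uncertainty
# ---------------------------------------------------------------------------


def mc_entropy(t: int, T: int) -> float:
    """Binary entropy (natural log) of the MC-dropout agreement fraction:
    H = -((t/T) ln(t/T) + ((T-t)/T) ln((T-t)/T)), with 0 ln 0 = 0.
    Zero iff t is 0 or T; maximal (ln 2) at t = T/2."""
    if not 0 <= t <= T:
        raise ValueError("t must satisfy 0 <= t <= T")
    f = t / T
    out = 0.0
    for q in (f, 1.0 - f):
        if q > 0.0:
            out -= q * np.log(q)
    return float(out)


def uncertainty_scores(
    model: TrainedGroupModel,
    X: np.ndarray,
    truth: dict[str, np.ndarray] | None = None,
    T: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-individual, per-gene uncertainty and correctness table.

    ``entropy`` is the MC-dropout sampling entropy of the diploid best-guess
    genotype; ``genotype_prob`` is the deterministic posterior probability of
    that genotype (product of the two haplotype argmax probabilities), the
    dosage-based discrimination score.  If ``truth`` is given, ``correct``
    flags exact (unordered) genotype agreement.
    """
    n = X.shape[0] // 2
    det = impute(model, X)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        Xi = X[2 * i : 2 * i + 2]
        samples = mc_dropout_sample(model, Xi, T=T, seed=int(rng.integers(2**31)))
        for g in model.genes:
            p = det.probs[g][2 * i : 2 * i + 2]
            arg = p.argmax(axis=1)
            names = model.alleles[g]
            bg = tuple(sorted((names[arg[0]], names[arg[1]])))
            t = sum(s == bg for s in samples[g])
            row = {
                "individual": i, "gene": g, "t": int(t), "T": T,
                "entropy": mc_entropy(int(t), T),
                "genotype_prob": float(p[0, arg[0]] * p[1, arg[1]]),
                "best_guess": "/".join(bg),
            }
            if truth is not None:
                tp = truth[g][i]
                row["truth_known"] = UNKNOWN not in tp
                row["correct"] = bool(set(bg) == set(tp)) if row["truth_known"] else None
            rows.append(row)
    return pd.DataFrame(rows)


def uncertainty_roc(scores: np.ndarray, correct: np.ndarray, mode: str = "entropy") -> float:
    """ROC-AUC for discriminating incorrectly imputed genotypes.

    ``mode="entropy"``: higher score = more likely incorrect (used as-is).
    ``mode="dosage"``: scores are best-guess genotype probabilities; the
    negative is ranked.  Midrank (Mann-Whitney) convention for ties; NaN
    (flagged) when only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    incorrect = ~np.asarray(correct, dtype=bool)
    if incorrect.all() or (~incorrect).all():
        warnings.warn("single-class labels; ROC-AUC undefined")
        return float("nan")
    if mode == "dosage":
        s = -s
    elif mode != "entropy":
        raise ValueError(f"unknown mode {mode!r}")
    ranks = stats.rankdata(s)  # midranks
    n1 = int(incorrect.sum())
    n0 = len(s) - n1
    u = ranks[incorrect].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
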