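"""Dosage construction and imputation-accuracy metrics.

Accuracy follows the dosage-based convention used for HLA imputation
benchmarking: per-locus sensitivity is the imputed dosage mass credited to
the true allele pair of each individual (alleles arranged to maximise
consistency with the truth), PPV is the credited mass over the total imputed
mass of an allele, r2 is the squared Pearson correlation of imputed versus
typed per-individual dosage, and the concordance rate applies the
sensitivity formula to hard best-guess calls.  Locus- and frequency-bin
aggregates are allele-frequency-weighted means, with r2 averaged through
Fisher's z-transform of the signed correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import UNKNOWN, AminoAcidDictionary, DosageTable, GeneGroup, PhasedPanel
from .model import (
    AlleleProbabilities,
    ModelHyperparams,
    TrainedGroupModel,
    impute,
    train_group,
)
from .panel import encode_window

logger = logging.getLogger(__name__)

DEFAULT_FREQ_BINS = (0.005, 0.01, 0.02, 0.05, 0.1, 0.5, 1.0)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

def truth_genotypes(panel: PhasedPanel, gene: str, res: int = 4) -> np.ndarray:
    """Unordered truth allele pairs per individual, shape (n, 2)."""
    lab = panel.hla_labels[gene][res]
    return lab.reshape(-1, 2).copy()


# ---------------------------------------------------------------------------
# dosage construction
# ---------------------------------------------------------------------------

def diploid_dosage(probs: AlleleProbabilities) -> DosageTable:
    """Classical-allele dosages: the two haplotype probabilities summed, so
    every gene's dosages total exactly 2 per individual."""
    rows, meta = {}, []
    for g in probs.genes:
        p = probs.probs[g]
        d = p[0::2] + p[1::2]
        for j, a in enumerate(probs.alleles[g]):
            vid = f"HLA_{g}_{a.replace(':', '')}"
            rows[vid] = d[:, j]
            meta.append((vid, "classical_allele", g, np.nan, a, np.nan))
    values = pd.DataFrame(rows, index=probs.sample_ids).T
    meta_df = pd.DataFrame(
        meta, columns=["id", "vclass", "gene", "position", "allele", "pos_bp"]
    ).set_index("id")
    return DosageTable(values, meta_df)


def derive_aa_dosages(
    classical: DosageTable, aa_dict: AminoAcidDictionary
) -> tuple[DosageTable, pd.DataFrame]:
    """Residue dosages from 4-digit classical dosages.

    The dosage of residue *r* at a position is the summed dosage of the
    4-digit alleles carrying *r* there, which keeps residue dosages
    consistent with classical alleles (they sum to 2 at fully covered
    positions).  Classical dosage mass on alleles absent from the dictionary
    is returned per (gene, position) as flagged "uncovered" mass.
    """
    rows, meta, uncovered = {}, [], []
    for gene in aa_dict.genes():
        ids = [
            vid for vid in classical.rows("classical_allele", gene)
            if classical.meta.loc[vid, "allele"].count(":") == 1  # 4-digit
        ]
        if not ids:
            continue
        allele_of = {vid: classical.meta.loc[vid, "allele"] for vid in ids}
        for p in aa_dict.positions(gene):
            residues = aa_dict.residues_at(gene, p)
            covered = [
                vid for vid in ids if aa_dict.residue(gene, allele_of[vid], p) is not None
            ]
            if not covered:
                warnings.warn(f"{gene} position {p}: no covered allele; skipped")
                continue
            mass = np.zeros(len(classical.sample_ids))
            for r in residues:
                carriers = [
                    vid for vid in covered
                    if aa_dict.residue(gene, allele_of[vid], p) == r
                ]
                d = classical.values.loc[carriers].sum(axis=0).to_numpy()
                vid = f"AA_{gene}_{p}_{r}"
                rows[vid] = d
                meta.append((vid, "residue_binary", gene, p, r, np.nan))
                mass += d
            miss = 2.0 - mass
            if np.any(miss > 1e-6):
                uncovered.append((gene, p, float(miss.max()), float(miss.mean())))
    values = pd.DataFrame(rows, index=classical.sample_ids).T
    meta_df = pd.DataFrame(
        meta, columns=["id", "vclass", "gene", "position", "allele", "pos_bp"]
    ).set_index("id")
    unc = pd.DataFrame(uncovered, columns=["gene", "position", "max_uncovered", "mean_uncovered"])
    return DosageTable(values, meta_df), unc


# ---------------------------------------------------------------------------
# best guess and pairing
# ---------------------------------------------------------------------------

def best_guess(probs: AlleleProbabilities) -> dict[str, np.ndarray]:
    """Per-haplotype argmax alleles as unordered pairs per individual.

    Exact probability ties break to the lexicographically first allele name
    (allele lists are sorted, so plain argmax implements the rule); ties are
    logged.
    """
    out = {}
    for g in probs.genes:
        p = probs.probs[g]
        arg = p.argmax(axis=1)
        tied = (p == p.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if tied.any():
            logger.info("best_guess: %d tied haplotype(s) at gene %s", int(tied.sum()), g)
        names = np.array(probs.alleles[g], dtype=object)
        out[g] = names[arg].reshape(-1, 2)
    return out


def optimal_pairing(guess_pair, truth_pair) -> int:
    """Matches between guessed and true allele pairs, maximised over the two
    assignments of guesses to truth slots (order-invariant)."""
    g1, g2 = guess_pair
    t1, t2 = truth_pair
    return max(int(g1 == t1) + int(g2 == t2), int(g1 == t2) + int(g2 == t1))


# ---------------------------------------------------------------------------
# per-gene metric engine
# ---------------------------------------------------------------------------

@dataclass
class _GeneAttribution:
    included: np.ndarray  # individual indices with known truth
    assigned: np.ndarray  # (2n,) truth allele assigned to each haplotype (object)
    p: np.ndarray  # (2n, K)
    names: list[str]
    index: dict[str, int]


def _attribute(p: np.ndarray, names: list[str], truth: np.ndarray) -> _GeneAttribution:
    """Assign each truth allele to the haplotype arrangement with maximal
    imputed support; individuals with unknown truth are excluded."""
    index = {a: i for i, a in enumerate(names)}
    n = truth.shape[0]
    assigned = np.full(2 * n, None, dtype=object)
    included = []
    for i in range(n):
        t1, t2 = truth[i]
        if t1 == UNKNOWN or t2 == UNKNOWN:
            continue
        included.append(i)
        h1, h2 = 2 * i, 2 * i + 1

        def d(h, a):
            j = index.get(a)
            return p[h, j] if j is not None else 0.0

        if d(h1, t1) + d(h2, t2) >= d(h1, t2) + d(h2, t1):
            assigned[h1], assigned[h2] = t1, t2
        else:
            assigned[h1], assigned[h2] = t2, t1
    return _GeneAttribution(np.array(included, dtype=int), assigned, p, names, index)


def _hap_dosage(att: _GeneAttribution, h: int, allele: str) -> float:
    j = att.index.get(allele)
    return float(att.p[h, j]) if j is not None else 0.0


def sensitivity_locus(att: _GeneAttribution) -> float:
    """Dosage mass credited to the truth alleles over 2n observations."""
    if att.included.size == 0:
        return float("nan")
    total = sum(
        _hap_dosage(att, h, att.assigned[h])
        for i in att.included
        for h in (2 * i, 2 * i + 1)
    )
    return total / (2 * att.included.size)


def sensitivity_allele(att: _GeneAttribution, allele: str) -> tuple[float, int]:
    """(Se(A), m): mean credited dosage over the m true carrier haplotypes."""
    carriers = [
        h for i in att.included for h in (2 * i, 2 * i + 1) if att.assigned[h] == allele
    ]
    if not carriers:
        return float("nan"), 0
    return float(np.mean([_hap_dosage(att, h, allele) for h in carriers])), len(carriers)


def ppv_allele(att: _GeneAttribution, allele: str) -> float:
    """Credited mass over total imputed mass of the allele."""
    carriers = {
        h for i in att.included for h in (2 * i, 2 * i + 1) if att.assigned[h] == allele
    }
    num = sum(_hap_dosage(att, h, allele) for h in carriers)
    den = sum(
        _hap_dosage(att, h, allele) for i in att.included for h in (2 * i, 2 * i + 1)
    )
    if den == 0.0:
        return float("nan")
    return num / den


def r_allele(att: _GeneAttribution, allele: str, truth: np.ndarray) -> float:
    """Signed Pearson correlation between imputed and typed diploid dosage;
    NaN (flagged) when either vector is constant."""
    j = att.index.get(allele)
    imputed, typed = [], []
    for i in att.included:
        d = att.p[2 * i, j] + att.p[2 * i + 1, j] if j is not None else 0.0
        imputed.append(d)
        typed.append(float((truth[i] == allele).sum()))
    imputed, typed = np.array(imputed), np.array(typed)
    if imputed.std() == 0.0 or typed.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(imputed, typed)[0, 1])


def _hard_call_probs(probs: AlleleProbabilities) -> AlleleProbabilities:
    hard = {}
    for g in probs.genes:
        p = probs.probs[g]
        h = np.zeros_like(p)
        h[np.arange(p.shape[0]), p.argmax(axis=1)] = 1.0
        hard[g] = h
    return AlleleProbabilities(probs.sample_ids, hard, dict(probs.alleles))


def accuracy_report(
    probs: AlleleProbabilities,
    truth: dict[str, np.ndarray],
    frequencies: dict[str, dict[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-allele and per-locus accuracy tables.

    ``truth[gene]`` is an (n, 2) unordered allele-pair array.  The
    concordance rate is the sensitivity recomputed on hard best-guess calls.
    Allele frequencies default to the truth-carrier frequency among included
    individuals; pass ``frequencies`` to weight by full-panel frequencies.
    Truth alleles never imputed by the model still appear (zero credit).
    """
    hard = _hard_call_probs(probs)
    allele_rows, locus_rows = [], []
    for g in probs.genes:
        att = _attribute(probs.probs[g], probs.alleles[g], truth[g])
        att_h = _attribute(hard.probs[g], probs.alleles[g], truth[g])
        n_incl = att.included.size
        truth_alleles = sorted(
            {a for i in att.included for a in truth[g][i]}
        )
        for a in sorted(set(truth_alleles) | set(probs.alleles[g])):
            se, m = sensitivity_allele(att, a)
            if m == 0:
                continue  # never truly observed: Se/PPV/CR undefined
            cr, _ = sensitivity_allele(att_h, a)
            r = r_allele(att, a, truth[g])
            freq = (
                frequencies[g].get(a, m / (2 * n_incl))
                if frequencies is not None
                else m / (2 * n_incl)
            )
            allele_rows.append(
                {
                    "gene": g, "allele": a, "freq": freq, "m": m, "n": n_incl,
                    "Se": se, "PPV": ppv_allele(att, a), "r": r,
                    "r2": r * r if np.isfinite(r) else np.nan, "CR": cr,
                }
            )
        locus_rows.append(
            {
                "gene": g, "n": n_incl,
                "Se": sensitivity_locus(att), "CR": sensitivity_locus(att_h),
            }
        )
    return pd.DataFrame(allele_rows), pd.DataFrame(locus_rows)


def concordance(probs: AlleleProbabilities, truth: dict[str, np.ndarray],
                gene: str) -> float:
    """Locus concordance rate of best-guess genotypes (optimally paired)."""
    hard = _hard_call_probs(probs)
    att = _attribute(hard.probs[gene], probs.alleles[gene], truth[gene])
    return sensitivity_locus(att)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _fisher_z_mean_r2(r: np.ndarray, w: np.ndarray) -> float:
    """Weighted Fisher-z mean of signed correlations, back-transformed and
    squared; +-1 clamped before atanh."""
    ok = np.isfinite(r)
    if not ok.any():
        return float("nan")
    r = np.clip(r[ok], -1 + 1e-12, 1 - 1e-12)
    w = w[ok]
    z = np.arctanh(r)
    return float(np.tanh(np.average(z, weights=w)) ** 2)


def aggregate(
    allele_report: pd.DataFrame,
    freq_bins: tuple[float, ...] = DEFAULT_FREQ_BINS,
) -> pd.DataFrame:
    """Frequency-weighted metric means within cumulative frequency bins
    (alleles with frequency <= each threshold, plus "all")."""
    out = []
    bins = [(f"<={b:g}", allele_report["freq"] <= b) for b in freq_bins]
    bins.append(("all", pd.Series(True, index=allele_report.index)))
    for label, mask in bins:
        sub = allele_report[mask]
        if sub.empty:
            continue
        w = sub["freq"].to_numpy()
        row = {"bin": label, "n_alleles": len(sub)}
        for metric in ("Se", "PPV", "CR"):
            vals = sub[metric].to_numpy()
            ok = np.isfinite(vals)
            row[metric] = float(np.average(vals[ok], weights=w[ok])) if ok.any() else np.nan
        row["r2"] = _fisher_z_mean_r2(sub["r"].to_numpy(), w)
        row["n_undefined_r2"] = int((~np.isfinite(sub["r"])).sum())
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# baseline imputer
# ---------------------------------------------------------------------------

def baseline_knn_impute(
    panel_train: PhasedPanel,
    target_X: np.ndarray,
    window_idx: np.ndarray,
    resolution: int = 4,
    sample_ids: list[str] | None = None,
) -> AlleleProbabilities:
    """1-nearest-haplotype imputation by Hamming distance within the window.

    The target allele gets probability 1 from its nearest training
    haplotype; exact distance ties split the mass evenly over the tied
    haplotypes' alleles.  ``target_X`` is a raw {0,1} haplotype matrix over
    the full variant set of the training panel.
    """
    if window_idx.size == 0:
        raise ValueError("empty window")
    train = panel_train.haplotypes[:, window_idx].astype(np.int64)
    targ = np.asarray(target_X)[:, window_idx].astype(np.int64)
    # pairwise Hamming distances
    dist = targ @ (1 - train.T) + (1 - targ) @ train.T
    probs, alleles = {}, {}
    for g in panel_train.genes:
        if resolution not in panel_train.hla_labels[g]:
            continue
        lab = panel_train.effective_labels(g, resolution)
        names = sorted(a for a in set(lab.tolist()) if a != UNKNOWN)
        index = {a: i for i, a in enumerate(names)}
        p = np.zeros((targ.shape[0], len(names)))
        for h in range(targ.shape[0]):
            tie = np.flatnonzero(dist[h] == dist[h].min())
            tie = [t for t in tie if lab[t] != UNKNOWN] or list(tie)
            for t in tie:
                if lab[t] != UNKNOWN:
                    p[h, index[lab[t]]] += 1.0
            if p[h].sum() == 0:
                p[h, :] = 1.0 / len(names)
            else:
                p[h] /= p[h].sum()
        probs[g], alleles[g] = p, names
    if sample_ids is None:
        sample_ids = [f"t{i}" for i in range(targ.shape[0] // 2)]
    return AlleleProbabilities(sample_ids, probs, alleles)


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

def cross_validate(
    panel: PhasedPanel,
    group: GeneGroup,
    hp: ModelHyperparams | None = None,
    k: int = 10,
    resolution: int = 4,
    seed: int = 0,
    imputer: str = "cnn",
    hierarchical: bool = False,
) -> tuple[AlleleProbabilities, pd.DataFrame, pd.DataFrame]:
    """k-fold cross-validated imputation with pooled metrics.

    Folds are assigned at the sample level; each round trains on k-1 folds
    (the early-stopping sub-validation split is drawn inside that training
    fold) and predicts the held-out samples, so every sample is predicted
    exactly once.  Held-out probabilities are pooled before metric
    computation and allele frequencies come from the full panel.
    ``imputer="knn"`` swaps in the 1-nearest-backbone baseline.
    """
    n = panel.n_samples
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(np.arange(n) % k)

    # full-panel allele lists and frequencies
    full_alleles: dict[str, list[str]] = {}
    freqs: dict[str, dict[str, float]] = {}
    genes = [g for g in group.genes if g in panel.hla_labels]
    for g in genes:
        lab = panel.effective_labels(g, resolution)
        names = sorted(a for a in set(lab.tolist()) if a != UNKNOWN)
        full_alleles[g] = names
        freqs[g] = {a: float((lab == a).mean()) for a in names}

    X_full, idx = encode_window(panel, group)
    pooled = {g: np.zeros((2 * n, len(full_alleles[g]))) for g in genes}
    for fold in range(k):
        test_samples = np.flatnonzero(fold_of == fold)
        train_samples = np.flatnonzero(fold_of != fold)
        sub = panel.subset_samples(list(train_samples))
        test_hap = np.concatenate([[2 * i, 2 * i + 1] for i in test_samples])
        if imputer == "cnn":
            if hp is None:
                raise ValueError("hp is required for the cnn imputer")
            init = (
                train_group(sub, group, hp, resolution=2) if hierarchical else None
            )
            model = train_group(sub, group, hp, resolution=resolution, init=init)
            fold_probs = impute(model, X_full[test_hap],
                                sample_ids=[panel.sample_ids[i] for i in test_samples])
        elif imputer == "knn":
            fold_probs = baseline_knn_impute(
                sub, panel.haplotypes[test_hap], idx, resolution=resolution,
                sample_ids=[panel.sample_ids[i] for i in test_samples])
        else:
            raise ValueError(f"unknown imputer {imputer!r}")
        for g in genes:
            if g not in fold_probs.probs:
                continue
            col = {a: j for j, a in enumerate(full_alleles[g])}
            for j_src, a in enumerate(fold_probs.alleles[g]):
                if a in col:
                    pooled[g][test_hap, col[a]] += fold_probs.probs[g][:, j_src]
    # renormalise rows whose fold model lacked some full-panel allele columns
    for g in genes:
        s = pooled[g].sum(axis=1, keepdims=True)
        s[s == 0.0] = 1.0
        pooled[g] /= s

    probs = AlleleProbabilities(list(panel.sample_ids), pooled, full_alleles)
    truth = {g: panel.effective_labels(g, resolution).reshape(-1, 2) for g in genes}
    allele_df, locus_df = accuracy_report(probs, truth, frequencies=freqs)
    return probs, allele_df, locus_df
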