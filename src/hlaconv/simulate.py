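"""Synthetic phased-panel and case-control cohort generator.

Real HLA reference panels are access-restricted, so every analysis in this
package is exercised on simulated panels that reproduce the statistical
structure the imputation model consumes: haplotype clusters (one SNV backbone
per classical allele), tunable SNV-tagging fidelity, a skewed allele-frequency
spectrum with rare alleles, a recombination mosaic along the map, optional
two-population structure with divergent frequencies and population-private
alleles, and a case-control cohort drawn from a logistic disease model on
true allele/residue dosages.  The generator targets these features, not
population-genetic realism (no coalescent, no mutation-rate calibration).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import (
    UNKNOWN,
    AminoAcidDictionary,
    DosageTable,
    GeneGroup,
    PhasedPanel,
    VariantRecord,
)

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


def _rng(seed_seq: np.random.SeedSequence, label: str) -> np.random.Generator:
    """Named, reproducible substream of a master seed (process-independent)."""
    key = zlib.crc32(label.encode())
    child = np.random.SeedSequence(entropy=seed_seq.entropy, spawn_key=(key,))
    return np.random.default_rng(child)


@dataclass
class SimConfig:
    """Study conditions for one simulated reference panel.

    Defaults give a cleanly decodable two-gene panel; noise knobs:

    ``tagging_fidelity``  probability that a haplotype carrying allele *a* is
        built from *a*'s own SNV backbone (else a random backbone) -- lower
        values weaken the SNV->allele association.
    ``snv_noise_rate``    per-SNV independent flip probability.
    ``recomb_switch_rate`` per-inter-SNV probability of switching to another
        allele's backbone (mosaic haplotypes).
    ``tag_placement``     where allele-distinguishing SNVs sit relative to the
        gene: "uniform" (whole backbone random), "near" (adjacent to the
        gene) or "far" (window edges) -- exercises the distance-dependent
        LD-decay analyses.
    """

    n_haplotypes: int = 400
    n_snvs_per_group: int = 80
    genes: tuple[str, ...] = ("G1", "G2")
    alleles_per_gene: dict[str, int] = field(default_factory=lambda: {"G1": 4, "G2": 4})
    freq_spectrum: float | dict[str, list[float]] = 0.8  # Dirichlet concentration
    tagging_fidelity: float = 1.0
    snv_noise_rate: float = 0.0
    recomb_switch_rate: float = 0.0
    n_populations: int = 1
    pop_divergence: float = 0.0
    pop_private_alleles: int = 0
    tag_placement: str = "uniform"
    n_tag_snvs: int = 6
    n_aa_positions: int = 4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.tagging_fidelity <= 1.0:
            raise ValueError("tagging_fidelity must be in [0, 1]")
        if not 0.0 <= self.snv_noise_rate < 1.0:
            raise ValueError("snv_noise_rate must be in [0, 1)")
        if not 0.0 <= self.recomb_switch_rate < 1.0:
            raise ValueError("recomb_switch_rate must be in [0, 1)")
        if self.n_populations not in (1, 2):
            raise ValueError("n_populations must be 1 or 2")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (two per sample)")
        if self.tag_placement not in ("uniform", "near", "far"):
            raise ValueError("tag_placement must be uniform/near/far")


@dataclass
class SimulatedReference:
    """A simulated panel plus the generating structure (for oracles)."""

    panel: PhasedPanel
    aa_dictionary: AminoAcidDictionary
    group: GeneGroup
    populations: np.ndarray  # per-sample population label
    backbones: dict[str, np.ndarray]  # gene -> (n_alleles, segment W) in window order
    segments: dict[str, np.ndarray]  # gene -> window-SNV indices of its segment
    tag_positions: dict[str, np.ndarray]  # gene -> distinguishing window-SNV indices
    frequencies: dict[str, dict[str, np.ndarray]]  # gene -> pop -> allele freqs
    alleles: dict[str, list[str]]  # gene -> ordered 4-digit allele names


def _allele_names(n: int) -> list[str]:
    """Hierarchical names: consecutive pairs share a 2-digit parent."""
    return [f"{i // 2 + 1:02d}:{i % 2 + 1:02d}" for i in range(n)]


def _gene_frequencies(cfg: SimConfig, gene: str, rng) -> np.ndarray:
    if isinstance(cfg.freq_spectrum, dict):
        f = np.asarray(cfg.freq_spectrum[gene], dtype=float)
        if len(f) != cfg.alleles_per_gene[gene]:
            raise ValueError(f"{gene}: {len(f)} frequencies for {cfg.alleles_per_gene[gene]} alleles")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError(f"{gene}: frequencies must sum to 1")
        return f
    f = rng.dirichlet(np.full(cfg.alleles_per_gene[gene], float(cfg.freq_spectrum)))
    return np.sort(f)[::-1]  # skewed spectrum: most common allele first


def _diverged(freqs: np.ndarray, scale: float, rng) -> np.ndarray:
    """Logit-normal perturbation of an allele-frequency vector."""
    logit = np.log(np.clip(freqs, 1e-6, None)) + rng.normal(0.0, scale, size=len(freqs))
    f = np.exp(logit)
    return f / f.sum()


def _tag_codes(k: int, n_tag: int, rng) -> np.ndarray:
    """Random binary tag patterns, one per allele, pairwise Hamming >= 2.

    Classical alleles differ at several linked SNVs, so a single genotyping
    error should not convert one allele's tag pattern into another's.
    """
    if k > 2 ** n_tag:
        raise ValueError(f"{k} alleles exceed 2^{n_tag} tag patterns")
    min_d = 2 if k <= 2 ** (n_tag - 1) else 1
    for _ in range(2000):
        codes = rng.integers(0, 2, size=(k, n_tag)).astype(np.uint8)
        d = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
        if (d[np.triu_indices(k, 1)] >= min_d).all():
            return codes
    raise RuntimeError("could not draw separated tag codes; increase n_tag_snvs")


def simulate_reference_panel(cfg: SimConfig) -> SimulatedReference:
    """Generate a phased panel with haplotype-cluster structure.

    Window SNVs are evenly spaced and partitioned into per-gene segments (a
    SNV belongs to the nearest gene).  Each 4-digit allele of a gene has a
    canonical binary backbone over that segment; haplotypes are backbone
    copies corrupted by tagging infidelity, recombination switching and
    per-SNV noise.  Deterministic given ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    n_genes = len(cfg.genes)
    W = cfg.n_snvs_per_group

    # geometry: SNVs every 1 kb; genes evenly placed in the interior
    base = 1_000_000
    positions = base + 1000 * np.arange(W)
    gene_pos = {
        g: int(positions[int((i + 0.5) / n_genes * (W - 1))])
        for i, g in enumerate(cfg.genes)
    }
    group = GeneGroup(
        name="synthetic",
        genes=list(cfg.genes),
        gene_pos=gene_pos,
        window_bp=int(positions[-1] - positions[0] + 1000),
    )
    variants = [
        VariantRecord(f"snv{j:04d}", "6", int(p), "A", "G") for j, p in enumerate(positions)
    ]

    # nearest-gene segment assignment
    gene_arr = np.array([gene_pos[g] for g in cfg.genes])
    owner = np.argmin(np.abs(positions[:, None] - gene_arr[None, :]), axis=1)
    segments = {g: np.flatnonzero(owner == i) for i, g in enumerate(cfg.genes)}

    alleles: dict[str, list[str]] = {}
    backbones: dict[str, np.ndarray] = {}
    tag_positions: dict[str, np.ndarray] = {}
    frequencies: dict[str, dict[str, np.ndarray]] = {}

    for g in cfg.genes:
        k = cfg.alleles_per_gene[g]
        seg = segments[g]
        rng_g = _rng(ss, f"backbone:{g}")
        if cfg.tag_placement == "uniform":
            if k > 2 ** len(seg):
                raise ValueError(f"{g}: {k} alleles exceed representable backbones")
            bb = rng_g.integers(0, 2, size=(k, len(seg))).astype(np.uint8)
            # ensure pairwise-distinct backbones
            while len({tuple(r) for r in bb}) < k:
                bb = rng_g.integers(0, 2, size=(k, len(seg))).astype(np.uint8)
            tags = seg.copy()
        else:
            n_tag = min(cfg.n_tag_snvs, len(seg))
            if k > 2 ** n_tag:
                raise ValueError(f"{g}: {k} alleles exceed 2^{n_tag} tag patterns")
            dist = np.abs(positions[seg] - gene_pos[g])
            order = np.argsort(dist, kind="stable")
            chosen = order[:n_tag] if cfg.tag_placement == "near" else order[::-1][:n_tag]
            base_vec = rng_g.integers(0, 2, size=len(seg)).astype(np.uint8)
            bb = np.tile(base_vec, (k, 1))
            codes = _tag_codes(k, n_tag, rng_g)
            for a in range(k):
                bb[a, chosen] = codes[a]
            tags = seg[np.sort(chosen)]
        alleles[g] = _allele_names(k)
        backbones[g] = bb
        tag_positions[g] = tags

        f = _gene_frequencies(cfg, g, _rng(ss, f"freq:{g}"))
        by_pop = {"pop1": f}
        if cfg.n_populations == 2:
            f2 = _diverged(f, cfg.pop_divergence, _rng(ss, f"freq2:{g}"))
            if cfg.pop_private_alleles:
                # rarest alleles of pop1 are absent from pop2
                private = np.argsort(f)[: cfg.pop_private_alleles]
                f2 = f2.copy()
                f2[private] = 0.0
                f2 = f2 / f2.sum()
            by_pop["pop2"] = f2
        frequencies[g] = by_pop

    # draw haplotypes
    n_hap = cfg.n_haplotypes
    n_samples = n_hap // 2
    pops = np.array(
        ["pop1"] * n_samples
        if cfg.n_populations == 1
        else ["pop1"] * (n_samples - n_samples // 2) + ["pop2"] * (n_samples // 2)
    )
    hap_pop = np.repeat(pops, 2)

    hap = np.zeros((n_hap, W), dtype=np.uint8)
    labels4: dict[str, np.ndarray] = {g: np.empty(n_hap, dtype=object) for g in cfg.genes}
    draw = _rng(ss, "draw")
    for g in cfg.genes:
        seg = segments[g]
        bb = backbones[g]
        k = bb.shape[0]
        for h in range(n_hap):
            f = frequencies[g][hap_pop[h]]
            a_true = draw.choice(k, p=f)
            labels4[g][h] = alleles[g][a_true]
            src = a_true if draw.random() < cfg.tagging_fidelity else draw.integers(k)
            row = np.empty(len(seg), dtype=np.uint8)
            cur = src
            for j in range(len(seg)):
                if j > 0 and cfg.recomb_switch_rate > 0 and draw.random() < cfg.recomb_switch_rate:
                    cur = draw.integers(k)
                row[j] = bb[cur, j]
            hap[h, seg] = row
    if cfg.snv_noise_rate > 0:
        noise = _rng(ss, "noise")
        flips = noise.random((n_hap, W)) < cfg.snv_noise_rate
        hap ^= flips.astype(np.uint8)

    hla_labels = {}
    for g in cfg.genes:
        lab2 = np.array([a.split(":")[0] for a in labels4[g]], dtype=object)
        hla_labels[g] = {2: lab2, 4: labels4[g]}

    panel = PhasedPanel(
        variants=variants,
        haplotypes=hap,
        sample_ids=[f"sim{i:05d}" for i in range(n_samples)],
        hla_labels=hla_labels,
    )

    aa_dict = _simulate_dictionary(cfg, alleles, ss)
    return SimulatedReference(
        panel=panel,
        aa_dictionary=aa_dict,
        group=group,
        populations=pops,
        backbones=backbones,
        segments=segments,
        tag_positions=tag_positions,
        frequencies=frequencies,
        alleles=alleles,
    )


def _simulate_dictionary(cfg: SimConfig, alleles, ss) -> AminoAcidDictionary:
    """Residues per 4-digit allele; position 1 separates every allele pair."""
    entries = {}
    for g in cfg.genes:
        names = alleles[g]
        if len(names) > len(_AA_ALPHABET):
            raise ValueError(f"{g}: more alleles than distinct residues at the anchor position")
        rng = _rng(ss, f"aa:{g}")
        for i, a in enumerate(names):
            res = {1: _AA_ALPHABET[i]}
            for p in range(2, cfg.n_aa_positions + 1):
                # low-cardinality polymorphic positions shared across alleles
                res[p] = "ST"[int(rng.integers(2))]
            entries[(g, a)] = res
    return AminoAcidDictionary(entries)


def mask_hla(panel: PhasedPanel) -> tuple[PhasedPanel, dict[str, dict[int, np.ndarray]]]:
    """Strip HLA labels (SNV-only target set); truth returned for scoring."""
    truth = {
        g: {r: lab.copy() for r, lab in by_res.items()}
        for g, by_res in panel.hla_labels.items()
    }
    masked = PhasedPanel(
        variants=list(panel.variants),
        haplotypes=panel.haplotypes.copy(),
        sample_ids=list(panel.sample_ids),
        hla_labels={},
    )
    return masked, truth


# ---------------------------------------------------------------------------
# case-control cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Logistic disease model: additive allele-dosage effects on log-odds.

    ``causal_effects`` keys:
        ("residue", gene, position, residue)  | ("allele", gene, allele_name)
        | ("snv", variant_id)
    mapping to log-odds per dosage unit.
    """

    n_cases: int
    n_controls: int
    causal_effects: dict[tuple, float] = field(default_factory=dict)
    intercept: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    n_pcs: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("case/control counts must be >= 1")


@dataclass
class SimulatedCohort:
    """Sampled diploid individuals with phenotype and covariates."""

    panel: PhasedPanel
    aa_dictionary: AminoAcidDictionary
    hap_index: np.ndarray  # (n, 2) row indices into panel.haplotypes
    phenotype: np.ndarray  # {0,1}
    covariates: pd.DataFrame
    population: np.ndarray  # per-individual labels
    sample_ids: list[str]

    def true_allele_dosage(self, gene: str, allele: str, res: int = 4) -> np.ndarray:
        lab = self.panel.hla_labels[gene][res]
        return (lab[self.hap_index[:, 0]] == allele).astype(float) + (
            lab[self.hap_index[:, 1]] == allele
        ).astype(float)

    def true_residue_dosage(self, gene: str, position: int, residue: str) -> np.ndarray:
        lab = self.panel.hla_labels[gene][4]
        d = self.aa_dictionary
        carrier = {a for a in self.panel.alleles(gene, 4) if d.residue(gene, a, position) == residue}
        out = np.zeros(len(self.hap_index))
        for c in (0, 1):
            out += np.isin(lab[self.hap_index[:, c]].astype(str), list(carrier)).astype(float)
        return out

    def snv_dosage(self, variant_id: str) -> np.ndarray:
        j = next(i for i, v in enumerate(self.panel.variants) if v.id == variant_id)
        col = self.panel.haplotypes[:, j]
        return col[self.hap_index[:, 0]].astype(float) + col[self.hap_index[:, 1]].astype(float)

    def snv_haplotypes(self) -> np.ndarray:
        """Phased SNV matrix of the cohort, shape (2n, n_variants)."""
        return self.panel.haplotypes[self.hap_index.reshape(-1)]

    def dosage_table(self, resolution: int = 4, include_snvs: bool = False) -> DosageTable:
        """Hard truth dosages for classical alleles, residues and (optionally)
        SNVs — the idealised analogue of perfectly imputed data."""
        rows, meta = {}, []
        panel = self.panel
        for gene in panel.genes:
            if resolution not in panel.hla_labels[gene]:
                continue
            for allele in panel.alleles(gene, resolution):
                vid = f"HLA_{gene}_{allele.replace(':', '')}"
                rows[vid] = self.true_allele_dosage(gene, allele, resolution)
                meta.append((vid, "classical_allele", gene, np.nan, allele, np.nan))
        for gene in self.aa_dictionary.genes():
            if gene not in panel.hla_labels or 4 not in panel.hla_labels[gene]:
                continue
            for p in self.aa_dictionary.positions(gene):
                for r in self.aa_dictionary.residues_at(gene, p):
                    vid = f"AA_{gene}_{p}_{r}"
                    rows[vid] = self.true_residue_dosage(gene, p, r)
                    meta.append((vid, "residue_binary", gene, p, r, np.nan))
        if include_snvs:
            hap = self.snv_haplotypes()
            for j, v in enumerate(panel.variants):
                col = hap[:, j].reshape(-1, 2).sum(axis=1).astype(float)
                rows[v.id] = col
                meta.append((v.id, "snv", "", np.nan, v.alt_allele, v.pos_bp))
        values = pd.DataFrame(rows, index=self.sample_ids).T
        meta_df = pd.DataFrame(
            meta, columns=["id", "vclass", "gene", "position", "allele", "pos_bp"]
        ).set_index("id")
        return DosageTable(values, meta_df)


def _linear_predictor(cohort_rows, spec, panel, aa_dict, hap_pair, cov_row) -> float:
    eta = spec.intercept
    for key, beta in spec.causal_effects.items():
        kind = key[0]
        if kind == "allele":
            _, gene, allele = key
            lab = panel.hla_labels[gene][4]
            d = float(lab[hap_pair[0]] == allele) + float(lab[hap_pair[1]] == allele)
        elif kind == "residue":
            _, gene, position, residue = key
            lab = panel.hla_labels[gene][4]
            d = sum(
                1.0
                for h in hap_pair
                if aa_dict.residue(gene, str(lab[h]), position) == residue
            )
        elif kind == "snv":
            _, vid = key
            j = cohort_rows[vid]
            d = float(panel.haplotypes[hap_pair[0], j]) + float(panel.haplotypes[hap_pair[1], j])
        else:
            raise ValueError(f"unknown causal-effect key {key!r}")
        eta += beta * d
    for name, beta in spec.covariate_effects.items():
        eta += beta * cov_row[name]
    return eta


def simulate_cohort(
    sim: SimulatedReference, spec: CohortSpec, max_attempts_factor: int = 500
) -> SimulatedCohort:
    """Draw a case-control cohort from the logistic model on true dosages.

    Individuals are random haplotype pairs from the panel (population-specific
    pools in two-population mode); case/control status is Bernoulli on the
    logistic scale, and sampling continues until both strata are filled.
    """
    panel, aa_dict = sim.panel, sim.aa_dictionary
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    snv_index = {v.id: j for j, v in enumerate(panel.variants)}

    hap_pool = {
        p: np.flatnonzero(np.repeat(sim.populations, 2) == p)
        for p in np.unique(sim.populations)
    }
    pops = sorted(hap_pool)
    n_target = spec.n_cases + spec.n_controls
    max_attempts = max_attempts_factor * n_target

    cases, controls = [], []
    attempts = 0
    while (len(cases) < spec.n_cases or len(controls) < spec.n_controls) and attempts < max_attempts:
        attempts += 1
        pop = pops[int(rng.integers(len(pops)))]
        pair = rng.choice(hap_pool[pop], size=2, replace=True)
        cov = {"sex": float(rng.integers(2))}
        for k in range(1, spec.n_pcs + 1):
            cov[f"PC{k}"] = float(rng.normal())
        cov["population"] = float(pop != pops[0])
        eta = _linear_predictor(snv_index, spec, panel, aa_dict, pair, cov)
        y = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
        bucket = cases if y else controls
        want = spec.n_cases if y else spec.n_controls
        if len(bucket) < want:
            bucket.append((pair, cov, pop))
    if len(cases) < spec.n_cases or len(controls) < spec.n_controls:
        raise RuntimeError(
            f"could not fill cohort strata after {attempts} draws "
            f"({len(cases)}/{spec.n_cases} cases, {len(controls)}/{spec.n_controls} controls)"
        )

    records = [(1, *c) for c in cases] + [(0, *c) for c in controls]
    phenotype = np.array([r[0] for r in records])
    hap_index = np.array([r[1] for r in records])
    cov_df = pd.DataFrame([r[2] for r in records]).drop(columns=["population"])
    population = np.array([r[3] for r in records])
    sample_ids = [f"ind{i:05d}" for i in range(len(records))]
    cov_df.index = sample_ids
    return SimulatedCohort(
        panel=panel,
        aa_dictionary=aa_dict,
        hap_index=hap_index,
        phenotype=phenotype,
        covariates=cov_df,
        population=population,
        sample_ids=sample_ids,
    )
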