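"""Phased reference-panel containers and file dialects.

The MHC imputation workflow consumes a *phased* reference panel: a binary
haplotype matrix over SNVs together with classical HLA allele labels for each
haplotype at one or more digit resolutions (2-digit allele group, 4-digit
protein, 6-digit synonymous).  Panels circulate in a SNP2HLA/Beagle-style
phased text dialect in which classical alleles are encoded as binary
present/absent (``P``/``A``) markers named ``HLA_<GENE>_<digits>``; this module
parses that dialect (plus an equivalent phased VCF with a sidecar label file),
normalises the allele labels into colon-separated form, and exposes the
one-hot window encoding the network trains on.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN = "unknown"

_HLA_MARKER_RE = re.compile(r"^HLA_([A-Za-z0-9]+)_(\d{2}|\d{4}|\d{6})$")


class PanelParseError(ValueError):
    """Raised when a panel file violates its dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with 1-based coordinates (VCF convention)."""

    id: str
    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.pos_bp < 1:
            raise ValueError(f"variant {self.id}: pos_bp must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"variant {self.id}: ref == alt ({self.ref_allele})")


@dataclass
class GeneGroup:
    """A set of neighbouring HLA genes imputed jointly by one multitask model.

    The model window spans from ``min(gene position) - window_bp`` to
    ``max(gene position) + window_bp`` (1-based, inclusive on both ends).
    """

    name: str
    genes: list[str]
    gene_pos: dict[str, int]
    window_bp: int = 500_000

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"group {self.name}: empty gene list")
        if self.window_bp <= 0:
            raise ValueError(f"group {self.name}: window_bp must be > 0")
        missing = [g for g in self.genes if g not in self.gene_pos]
        if missing:
            raise ValueError(f"group {self.name}: no coordinate for {missing}")

    @property
    def span(self) -> tuple[int, int]:
        pos = [self.gene_pos[g] for g in self.genes]
        return (min(pos) - self.window_bp, max(pos) + self.window_bp)


def normalize_allele(digits: str) -> str:
    """``"0101"`` -> ``"01:01"``; already-normalised names pass through."""
    if ":" in digits:
        return digits
    if len(digits) not in (2, 4, 6) or not digits.isdigit():
        raise ValueError(f"cannot normalise allele digit string {digits!r}")
    return ":".join(digits[i:i + 2] for i in range(0, len(digits), 2))


def allele_resolution(name: str) -> int:
    """Digit resolution (2/4/6) of a colon-separated allele name."""
    return 2 * (name.count(":") + 1)


@dataclass
class PhasedPanel:
    """Phased haplotypes over position-sorted SNVs with HLA truth labels.

    ``haplotypes`` is a {0,1} matrix with one row per haplotype (two adjacent
    rows per sample: ``2*i`` and ``2*i+1``) and one column per variant (0 =
    ref allele, 1 = alt allele).  ``hla_labels[gene][res]`` is an object array
    of per-haplotype allele names; ``"unknown"`` marks untyped haplotypes.
    """

    variants: list[VariantRecord]
    haplotypes: np.ndarray
    sample_ids: list[str]
    hla_labels: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)
    # (sample_id, gene, res, reason) tuples accumulated during parsing
    inconsistencies: list[tuple[str, str, int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype count must equal 2 x sample count")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("haplotype width must equal variant count")
        if len({v.id for v in self.variants}) != len(self.variants):
            raise ValueError("variant ids must be unique")
        order = np.argsort([v.pos_bp for v in self.variants], kind="stable")
        if not np.array_equal(order, np.arange(len(self.variants))):
            self.variants = [self.variants[i] for i in order]
            self.haplotypes = self.haplotypes[:, order]

    # -- basic views -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos_bp for v in self.variants], dtype=np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.hla_labels)

    def resolutions(self, gene: str) -> list[int]:
        return sorted(self.hla_labels.get(gene, {}))

    def alleles(self, gene: str, res: int) -> list[str]:
        """Sorted distinct allele names at a resolution (unknown excluded)."""
        lab = self.hla_labels[gene][res]
        return sorted(a for a in set(lab.tolist()) if a != UNKNOWN)

    def allele_frequency(self, gene: str, res: int, allele: str) -> float:
        lab = self.hla_labels[gene][res]
        typed = lab != UNKNOWN
        if not typed.any():
            return float("nan")
        return float((lab[typed] == allele).mean())

    def effective_labels(self, gene: str, res: int) -> np.ndarray:
        """Labels at ``res``, falling back to the coarser resolution where
        the finer one is untyped (the upper-resolution label is duplicated
        downward to keep hierarchical levels aligned across genes)."""
        out = self.hla_labels[gene].get(res, np.full(self.n_haplotypes, UNKNOWN, dtype=object)).copy()
        for coarser in sorted((r for r in self.hla_labels[gene] if r < res), reverse=True):
            missing = out == UNKNOWN
            if not missing.any():
                break
            out[missing] = self.hla_labels[gene][coarser][missing]
        return out

    def subset_samples(self, keep: list[int]) -> "PhasedPanel":
        hap_idx = np.array([[2 * i, 2 * i + 1] for i in keep], dtype=int).reshape(-1)
        labels = {
            g: {r: lab[hap_idx].copy() for r, lab in by_res.items()}
            for g, by_res in self.hla_labels.items()
        }
        kept_ids = {self.sample_ids[i] for i in keep}
        return PhasedPanel(
            variants=list(self.variants),
            haplotypes=self.haplotypes[hap_idx].copy(),
            sample_ids=[self.sample_ids[i] for i in keep],
            hla_labels=labels,
            inconsistencies=[t for t in self.inconsistencies if t[0] in kept_ids],
        )

    # -- window encoding ---------------------------------------------------
    def window_index(self, group: GeneGroup) -> np.ndarray:
        lo, hi = group.span
        pos = self.positions
        return np.flatnonzero((pos >= lo) & (pos <= hi))


def encode_window(panel: PhasedPanel, group: GeneGroup) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encode the SNVs inside a group's window.

    Returns ``(X, idx)`` where ``X`` has shape ``(n_haplotypes, 2, W)`` with
    channel 0 set where the haplotype carries the reference allele and channel
    1 where it carries the alternative; every column sums to exactly 1.
    """
    idx = panel.window_index(group)
    if idx.size == 0:
        raise ValueError(f"group {group.name}: no SNVs inside window span {group.span}")
    sub = panel.haplotypes[:, idx]
    X = np.zeros((sub.shape[0], 2, sub.shape[1]), dtype=np.float64)
    X[:, 0, :] = sub == 0
    X[:, 1, :] = sub == 1
    return X, idx


# ---------------------------------------------------------------------------
# amino-acid dictionary
# ---------------------------------------------------------------------------

@dataclass
class AminoAcidDictionary:
    """Maps (gene, 4-digit allele) to the residue at each covered position."""

    entries: dict[tuple[str, str], dict[int, str]] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.entries})

    def alleles(self, gene: str) -> list[str]:
        return sorted(a for g, a in self.entries if g == gene)

    def positions(self, gene: str) -> list[int]:
        pos: set[int] = set()
        for (g, _), res in self.entries.items():
            if g == gene:
                pos.update(res)
        return sorted(pos)

    def residue(self, gene: str, allele: str, position: int) -> str | None:
        return self.entries.get((gene, allele), {}).get(position)

    def residues_at(self, gene: str, position: int) -> list[str]:
        out = {
            res[position]
            for (g, _), res in self.entries.items()
            if g == gene and position in res
        }
        return sorted(out)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (g, a, p, r)
            for (g, a), res in sorted(self.entries.items())
            for p, r in sorted(res.items())
        ]
        pd.DataFrame(rows, columns=["gene", "allele", "position", "residue"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AminoAcidDictionary":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "allele": str, "residue": str})
        entries: dict[tuple[str, str], dict[int, str]] = {}
        for row in df.itertuples(index=False):
            entries.setdefault((row.gene, row.allele), {})[int(row.position)] = row.residue
        return cls(entries)


# ---------------------------------------------------------------------------
# Beagle phased dialect
# ---------------------------------------------------------------------------
# Header line:   I id s1 s1 s2 s2 ...
# Marker lines:  M <id> <a> <a> ...    (one allele column per haplotype)
# HLA markers are named HLA_<GENE>_<digits> and coded P (present) / A (absent).
# Positions and ref/alt alleles for SNVs travel in a sidecar ``.markers`` file
# with columns: id, pos_bp, allele1(ref), allele2(alt)  (SNP2HLA convention).

def read_phased_panel(
    path: str | Path,
    dialect: str = "beagle_phased",
    markers_path: str | Path | None = None,
    labels_path: str | Path | None = None,
    chrom: str = "6",
) -> PhasedPanel:
    """Read a phased reference panel.

    ``beagle_phased`` requires a sidecar markers file (default: ``path`` with a
    ``.markers`` suffix).  ``phased_vcf`` requires phased GT fields and takes
    HLA labels from a sidecar TSV (sample, hap_index, gene, resolution,
    allele) given as ``labels_path``.
    """
    if dialect == "beagle_phased":
        if markers_path is None:
            markers_path = Path(path).with_suffix(".markers")
        return _read_beagle(path, markers_path, chrom)
    if dialect == "phased_vcf":
        return _read_phased_vcf(path, labels_path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_markers(markers_path) -> dict[str, tuple[int, str, str]]:
    table: dict[str, tuple[int, str, str]] = {}
    with open(markers_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PanelParseError(f"{markers_path}:{ln}: expected 4 columns, got {len(parts)}")
            table[parts[0]] = (int(parts[1]), parts[2], parts[3])
    return table


def _read_beagle(path, markers_path, chrom) -> PhasedPanel:
    markers = _read_markers(markers_path)
    sample_ids: list[str] = []
    snv_records: list[VariantRecord] = []
    snv_rows: list[np.ndarray] = []
    # per (gene, res, haplotype): list of present alleles
    present: dict[tuple[str, int], list[list[str]]] = {}
    n_hap = None

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            tag = parts[0]
            if tag == "I":
                ids = parts[2:]
                if len(ids) % 2 or any(ids[i] != ids[i + 1] for i in range(0, len(ids), 2)):
                    raise PanelParseError(f"{path}:{ln}: sample ids must appear in adjacent pairs")
                sample_ids = ids[::2]
                n_hap = len(ids)
            elif tag == "M":
                if n_hap is None:
                    raise PanelParseError(f"{path}:{ln}: marker line before header")
                mid, alleles = parts[1], parts[2:]
                if len(alleles) != n_hap:
                    raise PanelParseError(
                        f"{path}:{ln}: marker {mid} has {len(alleles)} allele columns, expected {n_hap}"
                    )
                m = _HLA_MARKER_RE.match(mid)
                if m:
                    gene, digits = m.group(1), m.group(2)
                    res = len(digits)
                    name = normalize_allele(digits)
                    key = (gene, res)
                    if key not in present:
                        present[key] = [[] for _ in range(n_hap)]
                    for h, a in enumerate(alleles):
                        if a in ("P", "p"):
                            present[key][h].append(name)
                        elif a not in ("A", "a"):
                            raise PanelParseError(
                                f"{path}:{ln}: HLA marker {mid} allele {a!r} is not P/A"
                            )
                else:
                    if mid not in markers:
                        raise PanelParseError(f"{path}:{ln}: SNV {mid} missing from markers file")
                    pos, ref, alt = markers[mid]
                    codes = np.empty(n_hap, dtype=np.uint8)
                    for h, a in enumerate(alleles):
                        if a == ref:
                            codes[h] = 0
                        elif a == alt:
                            codes[h] = 1
                        else:
                            raise PanelParseError(
                                f"{path}:{ln}: SNV {mid} allele {a!r} is neither ref "
                                f"{ref!r} nor alt {alt!r} (multiallelic or missing "
                                "genotypes are not supported in reference panels)"
                            )
                    snv_records.append(VariantRecord(mid, chrom, pos, ref, alt))
                    snv_rows.append(codes)
            else:
                raise PanelParseError(f"{path}:{ln}: unknown line tag {tag!r}")

    if n_hap is None:
        raise PanelParseError(f"{path}: no header line")

    hla_labels, incons = _labels_from_present(present, sample_ids, n_hap)
    hap = (
        np.stack(snv_rows, axis=1)
        if snv_rows
        else np.zeros((n_hap, 0), dtype=np.uint8)
    )
    return PhasedPanel(snv_records, hap, sample_ids, hla_labels, incons)


def _labels_from_present(present, sample_ids, n_hap):
    hla_labels: dict[str, dict[int, np.ndarray]] = {}
    incons: list[tuple[str, str, int, str]] = []
    for (gene, res), per_hap in present.items():
        lab = np.full(n_hap, UNKNOWN, dtype=object)
        for h, names in enumerate(per_hap):
            if len(names) == 1:
                lab[h] = names[0]
            else:
                reason = "no_present_allele" if not names else "multiple_present_alleles"
                incons.append((sample_ids[h // 2], gene, res, reason))
        hla_labels.setdefault(gene, {})[res] = lab
    return hla_labels, incons


def write_phased_panel(
    panel: PhasedPanel,
    path: str | Path,
    markers_path: str | Path | None = None,
) -> None:
    """Write the Beagle phased dialect plus its sidecar markers file."""
    if markers_path is None:
        markers_path = Path(path).with_suffix(".markers")
    with open(markers_path, "w") as fh:
        for v in panel.variants:
            fh.write(f"{v.id}\t{v.pos_bp}\t{v.ref_allele}\t{v.alt_allele}\n")
    with open(path, "w") as fh:
        cols = " ".join(s for sid in panel.sample_ids for s in (sid, sid))
        fh.write(f"I id {cols}\n")
        for j, v in enumerate(panel.variants):
            alleles = np.where(panel.haplotypes[:, j] == 0, v.ref_allele, v.alt_allele)
            fh.write(f"M {v.id} " + " ".join(alleles) + "\n")
        for gene, by_res in panel.hla_labels.items():
            for res, lab in by_res.items():
                for allele in panel.alleles(gene, res):
                    mid = f"HLA_{gene}_{allele.replace(':', '')}"
                    coded = np.where(lab == allele, "P", "A")
                    coded[lab == UNKNOWN] = "A"
                    fh.write(f"M {mid} " + " ".join(coded) + "\n")


def _read_phased_vcf(path, labels_path) -> PhasedPanel:
    sample_ids: list[str] = []
    records: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                sample_ids = parts[9:]
                continue
            if not sample_ids:
                raise PanelParseError(f"{path}:{ln}: data line before #CHROM header")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            if "," in alt:
                raise PanelParseError(f"{path}:{ln}: multiallelic variant {vid} not supported")
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            codes = np.empty(2 * len(sample_ids), dtype=np.uint8)
            for s, cell in enumerate(parts[9:]):
                gt = cell.split(":")[gt_i]
                if "|" not in gt:
                    raise PanelParseError(
                        f"{path}:{ln}: unphased or missing GT {gt!r} for sample "
                        f"{sample_ids[s]}; pre-phase the data upstream"
                    )
                a, b = gt.split("|")
                if a not in "01" or b not in "01":
                    raise PanelParseError(f"{path}:{ln}: GT {gt!r} is not biallelic 0/1")
                codes[2 * s], codes[2 * s + 1] = int(a), int(b)
            records.append(VariantRecord(vid, chrom, pos, ref, alt))
            rows.append(codes)
    hap = np.stack(rows, axis=1) if rows else np.zeros((2 * len(sample_ids), 0), dtype=np.uint8)
    panel = PhasedPanel(records, hap, sample_ids, {}, [])
    if labels_path is not None:
        _attach_labels(panel, labels_path)
    return panel


def _attach_labels(panel: PhasedPanel, labels_path) -> None:
    df = pd.read_csv(labels_path, sep="\t", dtype={"sample": str, "gene": str, "allele": str})
    sample_index = {s: i for i, s in enumerate(panel.sample_ids)}
    present: dict[tuple[str, int], list[list[str]]] = {}
    for row in df.itertuples(index=False):
        if row.sample not in sample_index:
            raise PanelParseError(f"label file references unknown sample {row.sample!r}")
        if int(row.hap_index) not in (1, 2):
            raise PanelParseError(f"hap_index must be 1 or 2, got {row.hap_index}")
        h = 2 * sample_index[row.sample] + int(row.hap_index) - 1
        key = (row.gene, int(row.resolution))
        if key not in present:
            present[key] = [[] for _ in range(panel.n_haplotypes)]
        present[key][h].append(normalize_allele(str(row.allele)))
    labels, incons = _labels_from_present(present, panel.sample_ids, panel.n_haplotypes)
    panel.hla_labels = labels
    panel.inconsistencies = incons


def write_hla_labels(panel: PhasedPanel, path: str | Path) -> None:
    rows = []
    for gene, by_res in panel.hla_labels.items():
        for res, lab in by_res.items():
            for h, allele in enumerate(lab):
                if allele == UNKNOWN:
                    continue
                rows.append((panel.sample_ids[h // 2], h % 2 + 1, gene, res, allele))
    pd.DataFrame(rows, columns=["sample", "hap_index", "gene", "resolution", "allele"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# dosage tables
# ---------------------------------------------------------------------------

VARIANT_CLASSES = ("classical_allele", "residue_binary", "position_multiallelic", "snv")


@dataclass
class DosageTable:
    """Per-individual allelic dosages in [0, 2].

    ``values``: DataFrame indexed by variant id with one column per sample.
    ``meta``: DataFrame indexed identically with columns ``vclass`` (one of
    ``VARIANT_CLASSES``), ``gene``, ``position`` (amino-acid position, NaN for
    classical/SNV), ``allele`` (allele name or residue letter) and ``pos_bp``.
    Multiallelic amino-acid positions are represented by their member
    ``residue_binary`` rows sharing a ``(gene, position)`` pair.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share an index")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def rows(self, vclass: str | None = None, gene: str | None = None) -> pd.Index:
        mask = pd.Series(True, index=self.meta.index)
        if vclass is not None:
            mask &= self.meta["vclass"] == vclass
        if gene is not None:
            mask &= self.meta["gene"] == gene
        return self.meta.index[mask]

    def position_residues(self, gene: str, position: int) -> pd.Index:
        m = (
            (self.meta["vclass"] == "residue_binary")
            & (self.meta["gene"] == gene)
            & (self.meta["position"] == position)
        )
        return self.meta.index[m]

    def concat(self, other: "DosageTable") -> "DosageTable":
        if list(self.values.columns) != list(other.values.columns):
            raise ValueError("sample columns differ")
        return DosageTable(
            pd.concat([self.values, other.values]),
            pd.concat([self.meta, other.meta]),
        )


def write_dosages(table: DosageTable, path: str | Path, format: str = "tsv") -> None:
    """Write a dosage table as TSV (4-decimal dosages) or VCF with DS fields."""
    if format == "tsv":
        out = table.meta.copy()
        vals = table.values.map(lambda x: f"{x:.4f}")
        out = pd.concat([out, vals], axis=1)
        out.index.name = "id"
        out.to_csv(path, sep="\t")
    elif format == "vcf_ds":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(table.sample_ids)
                + "\n"
            )
            for vid in table.values.index:
                pos = table.meta.loc[vid, "pos_bp"]
                pos = int(pos) if pd.notna(pos) else 0
                cells = "\t".join(f"{x:.4f}" for x in table.values.loc[vid])
                fh.write(f"6\t{pos}\t{vid}\tP\tA\t.\t.\t.\tDS\t{cells}\n")
    else:
        raise ValueError(f"unknown dosage format {format!r}")


def read_dosages(path: str | Path) -> DosageTable:
    """Read back a TSV written by :func:`write_dosages`."""
    df = pd.read_csv(path, sep="\t", index_col="id")
    meta_cols = ["vclass", "gene", "position", "allele", "pos_bp"]
    meta = df[meta_cols]
    values = df.drop(columns=meta_cols).astype(float)
    values.columns = values.columns.astype(str)
    return DosageTable(values, meta)


# ---------------------------------------------------------------------------
# consistency filtering
# ---------------------------------------------------------------------------

def exclude_inconsistent(panel: PhasedPanel) -> tuple[PhasedPanel, pd.DataFrame]:
    """Drop samples whose HLA labels are internally inconsistent.

    A sample is removed when any of its haplotypes (a) carried zero or more
    than one present allele for a gene/resolution that is typed in the panel,
    or (b) carries a finer-resolution allele name that is not an extension of
    its coarser-resolution name.  A gene/resolution untyped for *every*
    haplotype is dropped from the label set instead of removing samples.
    Returns the filtered panel and a report of removals with reasons.
    """
    labels = {
        g: {r: lab for r, lab in by_res.items() if (lab != UNKNOWN).any()}
        for g, by_res in panel.hla_labels.items()
    }
    labels = {g: by_res for g, by_res in labels.items() if by_res}
    dropped_res = {
        (g, r)
        for g, by_res in panel.hla_labels.items()
        for r in by_res
        if g not in labels or r not in labels[g]
    }

    reasons: dict[str, list[str]] = {}
    for sid, gene, res, why in panel.inconsistencies:
        if (gene, res) in dropped_res:
            continue
        reasons.setdefault(sid, []).append(f"{gene}({res}-digit): {why}")
    for gene, by_res in labels.items():
        resolutions = sorted(by_res)
        for coarse, fine in zip(resolutions, resolutions[1:]):
            lc, lf = by_res[coarse], by_res[fine]
            both = (lc != UNKNOWN) & (lf != UNKNOWN)
            for h in np.flatnonzero(both):
                if not str(lf[h]).startswith(str(lc[h])):
                    sid = panel.sample_ids[h // 2]
                    reasons.setdefault(sid, []).append(
                        f"{gene}: {fine}-digit {lf[h]} conflicts with {coarse}-digit {lc[h]}"
                    )

    keep = [i for i, sid in enumerate(panel.sample_ids) if sid not in reasons]
    report = pd.DataFrame(
        [(sid, "; ".join(sorted(set(why)))) for sid, why in sorted(reasons.items())],
        columns=["sample", "reason"],
    )
    if not keep:
        warnings.warn("exclude_inconsistent removed every sample")
    out = PhasedPanel(
        variants=list(panel.variants),
        haplotypes=panel.haplotypes.copy(),
        sample_ids=list(panel.sample_ids),
        hla_labels=labels,
        inconsistencies=list(panel.inconsistencies),
    )
    out = out.subset_samples(keep)
    out.inconsistencies = []
    return out, report
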