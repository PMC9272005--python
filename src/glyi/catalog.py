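"""Gene/transcript/protein catalog for the durum wheat glyoxalase I (GLYI) family.

The catalog holds one record per annotated gene, each with one or more
splice-variant transcripts and their protein products.  Records carry the
chromosome (1A..7B), genomic location, CDS length, exon count, protein
length, molecular weight, isoelectric point and the annotated Pfam
lactoylglutathione-lyase (PF00903) domain length.  A flat tab-separated
serialization is used so the printed family table can be shipped and
round-tripped losslessly.

Protein physicochemical calculators (average molecular weight, theoretical
pI by Henderson--Hasselbalch charge balance) are included here because the
catalog reports them per protein; both use config-overridable residue
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "PKA_SIDE_CHAIN",
    "PKA_NTERM",
    "PKA_CTERM",
    "DomainSpan",
    "ProteinRecord",
    "TranscriptRecord",
    "GeneRecord",
    "Catalog",
    "CatalogSummary",
    "CatalogError",
    "CatalogSchemaError",
    "AlphabetError",
    "load_catalog",
    "write_catalog",
    "summarize",
    "compute_mw",
    "compute_pi",
    "net_charge",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Average (not monoisotopic) residue masses in Da.
AVERAGE_RESIDUE_MASS: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: EMBOSS-style side-chain pKa values (acidic residues carry -1 when
#: deprotonated, basic residues +1 when protonated).
PKA_SIDE_CHAIN: Mapping[str, float] = {
    "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,   # acidic
    "H": 6.5, "K": 10.8, "R": 12.5,            # basic
}
PKA_NTERM = 8.6
PKA_CTERM = 3.6
_ACIDIC = frozenset("CDEY")
_BASIC = frozenset("HKR")


class CatalogError(ValueError):
    """Base error for catalog loading/validation problems."""


class CatalogSchemaError(CatalogError):
    """The file header does not match the documented column schema."""


class AlphabetError(CatalogError):
    """A protein sequence contains non-standard letters."""

    def __init__(self, sequence: str, positions: Sequence[int]):
        self.positions = list(positions)
        letters = sorted({sequence[p - 1] for p in self.positions})
        super().__init__(
            f"non-standard amino acid letter(s) {letters} at 1-based "
            f"position(s) {self.positions}"
        )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainSpan:
    """A PF00903 domain annotation in 1-based inclusive aa coordinates.

    Fixture-only records (the printed family table) report the domain
    length but not its span, so ``start``/``end`` may be ``None``.
    """

    length: int
    start: int | None = None
    end: int | None = None
    family_tag: str = "PF00903"

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None:
            if self.end - self.start + 1 != self.length:
                raise CatalogError(
                    f"domain span {self.start}-{self.end} inconsistent with "
                    f"length {self.length}"
                )
        if self.length < 1:
            raise CatalogError("domain length must be >= 1")


@dataclass
class ProteinRecord:
    protein_id: str
    length: int
    mw: float | None = None          # kDa
    pi: float | None = None          # pH units
    sequence: str | None = None
    domains: list[DomainSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise CatalogError(
                f"{self.protein_id}: length {self.length} != sequence "
                f"length {len(self.sequence)}"
            )
        if self.mw is not None and self.mw <= 0:
            raise CatalogError(f"{self.protein_id}: mw must be > 0")
        if self.pi is not None and not 0 < self.pi < 14:
            raise CatalogError(f"{self.protein_id}: pi must lie in (0, 14)")
        for span in self.domains:
            if span.end is not None and span.end > self.length:
                raise CatalogError(
                    f"{self.protein_id}: domain span exceeds protein length"
                )


@dataclass
class TranscriptRecord:
    transcript_id: str
    cds_length: int                  # bp, multiple of 3, includes stop codon
    exon_count: int
    protein: ProteinRecord

    def __post_init__(self) -> None:
        if self.cds_length < 3 or self.cds_length % 3:
            raise CatalogError(
                f"{self.transcript_id}: CDS length {self.cds_length} is not "
                "a positive multiple of 3"
            )
        if self.exon_count < 1:
            raise CatalogError(f"{self.transcript_id}: exon count must be >= 1")
        expected = self.cds_length // 3 - 1   # stop codon removed
        if self.protein.length != expected:
            raise CatalogError(
                f"{self.transcript_id}: protein length {self.protein.length} "
                f"!= CDS/3 - 1 = {expected}"
            )


@dataclass
class GeneRecord:
    gene_id: str
    chromosome: str                  # 1A..7B
    start: int
    end: int
    transcripts: list[TranscriptRecord]
    ensembl_gene: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CatalogError(f"{self.gene_id}: start > end")
        if not self.transcripts:
            raise CatalogError(f"{self.gene_id}: gene has no transcripts")

    @property
    def subgenome(self) -> str:
        return self.chromosome[-1]


@dataclass
class Catalog:
    genes: list[GeneRecord]

    @property
    def transcripts(self) -> list[TranscriptRecord]:
        return [t for g in self.genes for t in g.transcripts]

    @property
    def proteins(self) -> list[ProteinRecord]:
        return [t.protein for t in self.transcripts]

    def gene_of(self, protein_id: str) -> GeneRecord:
        for gene in self.genes:
            for t in gene.transcripts:
                if t.protein.protein_id == protein_id:
                    return gene
        raise KeyError(f"protein {protein_id!r} not in catalog")


@dataclass
class CatalogSummary:
    n_genes: int
    n_transcripts: int
    n_multi_splice_genes: int
    per_chromosome: dict[str, int]
    per_subgenome: dict[str, int]
    cds_min: int | None
    cds_max: int | None
    cds_mean: float | None

    @property
    def cds_mean_rounded(self) -> int | None:
        if self.cds_mean is None:
            return None
        return round(self.cds_mean)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

COLUMNS = [
    "chromosome", "gene_id", "ensembl_gene", "location", "transcript_id",
    "cds_bp", "exons", "protein_aa", "mw_kda", "pi", "domain_aa",
]


def load_catalog(path) -> Catalog:
    """Load a catalog from a tab-separated file.

    The file is flat: one row per transcript.  Gene-level columns may be
    left blank on continuation rows of a multi-transcript gene (they are
    forward-filled); the canonical writer fills every row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CatalogSchemaError(f"missing required column(s): {missing}")
    for col in ("chromosome", "gene_id", "ensembl_gene", "location"):
        df[col] = df[col].replace("", None).ffill()

    genes: dict[str, GeneRecord] = {}
    seen_tx: set[str] = set()
    problems: list[str] = []
    for i, row in df.iterrows():
        line_no = i + 2   # header is line 1
        try:
            tx_id = row["transcript_id"]
            if tx_id in seen_tx:
                raise CatalogError(f"duplicate transcript_id {tx_id!r}")
            seen_tx.add(tx_id)
            domain_field = row["domain_aa"].strip()
            domains = []
            if domain_field.lower() != "absent":
                domains = [DomainSpan(length=int(domain_field))]
            protein = ProteinRecord(
                protein_id=tx_id,
                length=int(row["protein_aa"]),
                mw=float(row["mw_kda"]),
                pi=float(row["pi"]),
                domains=domains,
            )
            transcript = TranscriptRecord(
                transcript_id=tx_id,
                cds_length=int(row["cds_bp"]),
                exon_count=int(row["exons"]),
                protein=protein,
            )
            gene_id = row["gene_id"]
            if gene_id in genes:
                genes[gene_id].transcripts.append(transcript)
            else:
                start_s, end_s = row["location"].replace("–", "-").split("-")
                genes[gene_id] = GeneRecord(
                    gene_id=gene_id,
                    chromosome=row["chromosome"],
                    start=int(start_s),
                    end=int(end_s),
                    transcripts=[transcript],
                    ensembl_gene=row["ensembl_gene"] or None,
                )
        except (CatalogError, ValueError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise CatalogError("malformed catalog rows:\n" + "\n".join(problems))
    return Catalog(genes=list(genes.values()))


def write_catalog(catalog: Catalog, path) -> None:
    """Write a catalog in canonical flat TSV form (every row fully filled)."""
    rows = []
    for gene in catalog.genes:
        for t in gene.transcripts:
            p = t.protein
            domain = str(p.domains[0].length) if p.domains else "Absent"
            rows.append({
                "chromosome": gene.chromosome,
                "gene_id": gene.gene_id,
                "ensembl_gene": gene.ensembl_gene or "",
                "location": f"{gene.start}-{gene.end}",
                "transcript_id": t.transcript_id,
                "cds_bp": t.cds_length,
                "exons": t.exon_count,
                "protein_aa": p.length,
                "mw_kda": p.mw,
                "pi": p.pi,
                "domain_aa": domain,
            })
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summarize(catalog: Catalog) -> CatalogSummary:
    """Per-family tallies: gene/transcript counts, chromosome and subgenome
    distribution, CDS length statistics.

    A gene is *multi-splice* when it has strictly more than one transcript.
    The CDS mean is the arithmetic mean over all transcripts (exact value
    stored; nearest-integer rounding exposed as ``cds_mean_rounded``).
    """
    cds = [t.cds_length for t in catalog.transcripts]
    per_chrom: dict[str, int] = {}
    per_sub: dict[str, int] = {}
    for g in catalog.genes:
        per_chrom[g.chromosome] = per_chrom.get(g.chromosome, 0) + 1
        per_sub[g.subgenome] = per_sub.get(g.subgenome, 0) + 1
    return CatalogSummary(
        n_genes=len(catalog.genes),
        n_transcripts=len(cds),
        n_multi_splice_genes=sum(
            1 for g in catalog.genes if len(g.transcripts) > 1
        ),
        per_chromosome=dict(sorted(per_chrom.items())),
        per_subgenome=dict(sorted(per_sub.items())),
        cds_min=min(cds) if cds else None,
        cds_max=max(cds) if cds else None,
        cds_mean=sum(cds) / len(cds) if cds else None,
    )


# ---------------------------------------------------------------------------
# physicochemical calculators
# ---------------------------------------------------------------------------

def _check_alphabet(sequence: str) -> None:
    if not sequence:
        raise CatalogError("sequence must be non-empty")
    bad = [i + 1 for i, aa in enumerate(sequence) if aa not in AMINO_ACIDS]
    if bad:
        raise AlphabetError(sequence, bad)


def compute_mw(sequence: str,
               residue_mass: Mapping[str, float] = AVERAGE_RESIDUE_MASS,
               water: float = WATER_MASS) -> float:
    """Average molecular weight of a protein, in kDa.

    Sum of average residue masses plus one water; additive up to the shared
    water term: mw(a + b) = mw(a) + mw(b) - water.
    """
    _check_alphabet(sequence)
    return (sum(residue_mass[aa] for aa in sequence) + water) / 1000.0


def net_charge(sequence: str, ph: float,
               pka_side: Mapping[str, float] = PKA_SIDE_CHAIN,
               pka_nterm: float = PKA_NTERM,
               pka_cterm: float = PKA_CTERM) -> float:
    """Net protein charge at a given pH (Henderson--Hasselbalch).

    Basic groups (N-terminus, H, K, R) contribute +1/(1 + 10^(pH-pKa)),
    acidic groups (C-terminus, D, E, C, Y) contribute -1/(1 + 10^(pKa-pH)).
    """
    pos = 1.0 / (1.0 + 10.0 ** (ph - pka_nterm))
    neg = 1.0 / (1.0 + 10.0 ** (pka_cterm - ph))
    for aa in sequence:
        if aa in _BASIC:
            pos += 1.0 / (1.0 + 10.0 ** (ph - pka_side[aa]))
        elif aa in _ACIDIC:
            neg += 1.0 / (1.0 + 10.0 ** (pka_side[aa] - ph))
    return pos - neg


def compute_pi(sequence: str,
               pka_side: Mapping[str, float] = PKA_SIDE_CHAIN,
               pka_nterm: float = PKA_NTERM,
               pka_cterm: float = PKA_CTERM,
               tol: float = 1e-4) -> float:
    """Theoretical isoelectric point: the pH of zero net charge.

    Found by bisection on [0, 14]; the charge function is strictly
    decreasing in pH so the root is unique.
    """
    _check_alphabet(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka_side, pka_nterm, pka_cterm) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
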