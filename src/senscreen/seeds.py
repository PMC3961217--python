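"""miRNA seed-site scanning and overlap with differential-expression lists.

Canonical miRNA target sites are defined by Watson-Crick complementarity
of a UTR window to the miRNA seed (nucleotides 2-8 of the mature strand).
On the UTR sense strand, written 5'->3', a site is laid out as

    [m8 match][complement of seed positions 7..2][A1]

i.e. the base opposite miRNA position 8 sits at the 5' end of the site
and the base opposite position 1 at its 3' end. Site types, strongest
first: 8mer (positions 2-8 matched plus an A opposite position 1),
7mer-m8 (positions 2-8 matched, no A), 7mer-A1 (positions 2-7 matched
plus the A), 6mer (positions 2-7 only). The A1 base is required to be a
genomic adenosine regardless of the miRNA's first nucleotide. Each core
match is reported once, typed as the strongest pattern it supports; only
exact matching is performed (no context scoring, conservation or
thermodynamics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SITE_TYPES",
    "MatureMiRNA",
    "SeedSite",
    "OverlapReport",
    "extract_seed",
    "scan_sites",
    "read_utr_fasta",
    "genes_with_sites",
    "overlap_with_de",
]

#: Site types ordered weakest to strongest.
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_RANK = {t: i for i, t in enumerate(SITE_TYPES)}


def _normalize(seq: str, what: str, allow_n: bool = False) -> str:
    s = seq.upper().replace("U", "T")
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA strand; the seed is positions 2-8 (1-based)."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = _normalize(self.sequence, f"miRNA {self.name}")
        if not 18 <= len(seq) <= 25:
            raise ValueError(
                f"miRNA {self.name}: mature length {len(seq)} outside 18-25 nt"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def seed(self) -> str:
        return extract_seed(self)


class SeedSite(NamedTuple):
    transcript_id: str
    start: int  # 0-based, half-open, UTR sense strand
    end: int
    site_type: str
    mirna: str


def extract_seed(mirna: "MatureMiRNA | str") -> str:
    """Nucleotides 2-8 (1-based) of the mature strand, uppercased, U->T."""
    seq = mirna.sequence if isinstance(mirna, MatureMiRNA) else _normalize(mirna, "miRNA")
    if len(seq) < 8:
        raise ValueError("mature sequence shorter than 8 nt has no seed")
    return seq[1:8]


def scan_sites(utr: str, mirna: MatureMiRNA, transcript_id: str = "") -> list[SeedSite]:
    """Find and type all seed-complementary sites in a sense-strand UTR.

    Every occurrence of the reverse complement of seed positions 2-7
    (the 6-mer core) yields exactly one site, typed by whether the
    flanking bases extend it to an m8 match and/or a genomic A opposite
    position 1. Windows containing N never match. Coordinates are 0-based
    half-open and span the full matched pattern (6, 7 or 8 nt).
    """
    s = _normalize(utr, f"UTR {transcript_id or '<anonymous>'}", allow_n=True)
    seed7 = extract_seed(mirna)
    rc7 = str(Seq(seed7).reverse_complement())
    rc6 = rc7[1:]
    m8c = rc7[0]
    L = len(s)
    sites: list[SeedSite] = []
    i = s.find(rc6)
    while i != -1:
        has_m8 = i > 0 and s[i - 1] == m8c
        has_a1 = i + 6 < L and s[i + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(transcript_id, i - 1, i + 7, "8mer", mirna.name))
        elif has_m8:
            sites.append(SeedSite(transcript_id, i - 1, i + 6, "7mer-m8", mirna.name))
        elif has_a1:
            sites.append(SeedSite(transcript_id, i, i + 7, "7mer-A1", mirna.name))
        else:
            sites.append(SeedSite(transcript_id, i, i + 6, "6mer", mirna.name))
        i = s.find(rc6, i + 1)
    return sites


def read_utr_fasta(path) -> dict[str, str]:
    """Read UTR sequences from FASTA; duplicate ids are an error."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def genes_with_sites(
    utrs: "Mapping[str, str] | str",
    mirna: MatureMiRNA,
    transcript_to_gene: Mapping[str, str] | None = None,
    min_type: str = "6mer",
) -> set[str]:
    """Genes whose UTR carries at least one site of ``min_type`` or stronger.

    ``utrs`` may be a transcript-id -> sequence mapping or a FASTA path.
    Without a transcript-to-gene mapping, transcript ids are used as gene
    ids directly.
    """
    if min_type not in _RANK:
        raise ValueError(f"min_type must be one of {SITE_TYPES}")
    if not isinstance(utrs, Mapping):
        utrs = read_utr_fasta(utrs)
    if len(set(utrs)) != len(utrs):
        raise ValueError("duplicate transcript ids")
    min_rank = _RANK[min_type]
    genes: set[str] = set()
    for tx, seq in utrs.items():
        gene = transcript_to_gene.get(tx, tx) if transcript_to_gene else tx
        if gene in genes:
            continue
        if any(_RANK[s.site_type] >= min_rank for s in scan_sites(seq, mirna, tx)):
            genes.add(gene)
    return genes


@dataclass
class OverlapReport:
    """Intersections of predicted target genes with DE gene lists."""

    n_targets: int
    n_de_up: int
    n_de_down: int
    n_up_and_target: int
    n_down_and_target: int
    membership: pd.DataFrame  # gene, in_targets, in_de_up, in_de_down

    def counts(self) -> dict[str, int]:
        return {
            "targets": self.n_targets,
            "de_up": self.n_de_up,
            "de_down": self.n_de_down,
            "de_up_and_target": self.n_up_and_target,
            "de_down_and_target": self.n_down_and_target,
        }


def overlap_with_de(
    target_genes: Iterable[str],
    de_up: Iterable[str],
    de_down: Iterable[str],
) -> OverlapReport:
    """Overlap predicted seed-containing genes with up/down DE lists.

    Returns exact set-intersection counts plus a per-gene membership
    table from which the counts can be reproduced (the inputs for a Venn
    diagram). A warning is emitted if the gene namespaces appear
    disjoint (non-empty inputs with zero overlap).
    """
    targets, up, down = set(target_genes), set(de_up), set(de_down)
    universe = sorted(targets | up | down)
    membership = pd.DataFrame(
        {
            "gene": universe,
            "in_targets": [g in targets for g in universe],
            "in_de_up": [g in up for g in universe],
            "in_de_down": [g in down for g in universe],
        }
    )
    up_and = targets & up
    down_and = targets & down
    if targets and (up or down) and not up_and and not down_and:
        warnings.warn(
            "no overlap between target genes and DE lists; "
            "check that gene identifiers share a namespace",
            stacklevel=2,
        )
    return OverlapReport(
        n_targets=len(targets),
        n_de_up=len(up),
        n_de_down=len(down),
        n_up_and_target=len(up_and),
        n_down_and_target=len(down_and),
        membership=membership,
    )
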