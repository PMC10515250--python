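"""Miniature SNV consequence annotator against exon/CDS gene models.

Classifies single-nucleotide variants relative to one or more transcript
models (multiple isoforms per gene are first-class): intergenic, intronic,
splice_site (within 2 bp of an intron boundary, on the intron side), UTR,
synonymous, missense, nonsense or stop_loss, with codon (AAG>AAT) and
protein (K114N) change notation for coding consequences.  A variant is
flagged deleterious when its class is missense, nonsense, stop_loss or
splice_site — the prioritization predicate used to single out
protein-altering candidates inside a mapped region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio import SeqIO

CONSEQUENCES = (
    "intergenic",
    "intronic",
    "splice_site",
    "utr",
    "synonymous",
    "missense",
    "nonsense",
    "stop_loss",
)
DELETERIOUS_CLASSES = frozenset({"missense", "nonsense", "stop_loss", "splice_site"})

# lower = more severe; used by prioritize()
SEVERITY = {
    "nonsense": 0,
    "stop_loss": 0,
    "splice_site": 0,
    "missense": 1,
    "synonymous": 2,
    "utr": 2,
    "intronic": 3,
    "intergenic": 4,
}

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon and CDS intervals (1-based closed, genomic order)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s, e) in ivs:
                if s > e:
                    raise ValueError(f"{self.transcript_id}: bad {name} interval {s}-{e}")
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"{self.transcript_id}: {name} intervals overlap or are unsorted"
                    )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def is_partial(self) -> bool:
        """CDS length not divisible by 3 after splicing."""
        return self.cds_length % 3 != 0


@dataclass(frozen=True)
class Effect:
    """Consequence of one SNV on one transcript (or intergenic)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str | None
    consequence: str
    codon_change: str | None = None
    protein_change: str | None = None
    deleterious: bool = False


def translate_codon(codon: str) -> str:
    """One-letter amino acid ('*' for stop) for a 3-base uppercase DNA codon."""
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"codon must be 3 uppercase DNA bases, got {codon!r}")
    table = CodonTable.unambiguous_dna_by_id[1]
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def classify_snv(
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    variant: tuple[str, int, str, str],
    splice_window: int = 2,
) -> list[Effect]:
    """Classify an SNV against every overlapping transcript.

    ``variant`` is (chrom, pos, ref, alt), 1-based.  The reference base must
    match the genome at that position.  Returns one Effect per overlapping
    transcript, or a single intergenic Effect when none overlaps.
    """
    chrom, pos, ref, alt = variant
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise ValueError(f"invalid SNV alleles {ref}>{alt}")
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {chrom}:{pos} outside sequence")
    if seq[pos - 1].upper() != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: genome has "
            f"{seq[pos - 1].upper()!r}, variant says {ref!r}"
        )
    effects = []
    for t in transcripts:
        if t.chrom != chrom:
            continue
        lo, hi = t.span
        if not lo <= pos <= hi:
            continue
        effects.append(_classify_in_transcript(seq, t, pos, ref, alt, splice_window))
    if not effects:
        effects.append(
            Effect(chrom, pos, ref, alt, None, "intergenic", deleterious=False)
        )
    return effects


def _classify_in_transcript(
    seq: str, t: TranscriptModel, pos: int, ref: str, alt: str, splice_window: int
) -> Effect:
    in_exon = any(s <= pos <= e for s, e in t.exons)
    if not in_exon:
        # intron: distance to the nearest flanking exon edge
        dist = min(
            min(abs(pos - e1), abs(s2 - pos))
            for (_, e1), (s2, _) in zip(t.exons, t.exons[1:])
            if e1 < pos < s2
        )
        cls = "splice_site" if dist <= splice_window else "intronic"
        return Effect(
            t.chrom, pos, ref, alt, t.transcript_id, cls,
            deleterious=cls in DELETERIOUS_CLASSES,
        )
    in_cds = any(s <= pos <= e for s, e in t.cds)
    if not in_cds:
        return Effect(t.chrom, pos, ref, alt, t.transcript_id, "utr")
    # coding: map the genomic position through the spliced CDS
    offset = 0
    for s, e in t.cds:
        if s <= pos <= e:
            offset += pos - s
            break
        offset += e - s + 1
    cds_seq = "".join(seq[s - 1 : e] for s, e in t.cds).upper()
    if t.strand == "-":
        cds_seq = cds_seq.translate(_COMPLEMENT)[::-1]
        ci = len(cds_seq) - 1 - offset
        alt_coding = alt.translate(_COMPLEMENT)
    else:
        ci = offset
        alt_coding = alt
    codon_i, within = divmod(ci, 3)
    codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    if len(codon) < 3:
        raise ValueError(
            f"{t.transcript_id}: variant falls in a partial terminal codon"
        )
    alt_codon = codon[:within] + alt_coding + codon[within + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(alt_codon)
    if aa_ref == aa_alt:
        cls = "synonymous"
    elif aa_ref == "*":
        cls = "stop_loss"
    elif aa_alt == "*":
        cls = "nonsense"
    else:
        cls = "missense"
    return Effect(
        t.chrom, pos, ref, alt, t.transcript_id, cls,
        codon_change=f"{codon}>{alt_codon}",
        protein_change=f"{aa_ref}{codon_i + 1}{aa_alt}",
        deleterious=cls in DELETERIOUS_CLASSES,
    )


@dataclass(frozen=True)
class VariantPriority:
    """A variant with its per-transcript effects, ranked by worst consequence."""

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str  # most severe across transcripts
    deleterious: bool
    effects: tuple[Effect, ...]


def prioritize(
    effects: Iterable[Effect], region_rank=None
) -> list[VariantPriority]:
    """Rank variants by worst-transcript consequence severity.

    Order: nonsense/splice_site/stop_loss, then missense, then
    synonymous/UTR, intronic, intergenic; within a class by ``region_rank``
    (an optional ``(chrom, pos) -> int`` callable, e.g. the rank of the
    candidate region the variant falls in) and then genomic position.  When
    a variant hits several isoforms the most severe effect wins, mirroring
    mutations in domains shared between splice variants.
    """
    by_variant: dict[tuple[str, int, str, str], list[Effect]] = {}
    for e in effects:
        by_variant.setdefault((e.chrom, e.pos, e.ref, e.alt), []).append(e)
    ranked = []
    for (chrom, pos, ref, alt), effs in by_variant.items():
        best = min(effs, key=lambda e: SEVERITY[e.consequence])
        ranked.append(
            VariantPriority(
                chrom, pos, ref, alt,
                consequence=best.consequence,
                deleterious=best.deleterious,
                effects=tuple(effs),
            )
        )
    ranked.sort(
        key=lambda v: (
            SEVERITY[v.consequence],
            region_rank(v.chrom, v.pos) if region_rank is not None else 0,
            v.chrom,
            v.pos,
        )
    )
    return ranked


def load_genome_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into {name: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def load_gene_models(path: str) -> list[TranscriptModel]:
    """Read transcript models (mRNA with exon/CDS children) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = tuple(
            sorted(
                (f.start, f.end)
                for f in db.children(mrna, featuretype="exon")
            )
        )
        cds = tuple(
            sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        )
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        models.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models
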