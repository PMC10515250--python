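"""Packaged fixtures: curated DEG tables and a synthetic two-isoform locus.

The DEG tables are clean transcriptions of the study's printed gene lists
(cuticle/cell-wall and hormone categories, with log2 fold changes and
q-values).  The locus fixture is *synthetic*: a small, fully specified
stand-in for the real SHN2-type gene, built so that the documented causal
change — a G>T transversion at the last base of the second exon turning
codon 114 (AAG, Lys) into AAT (Asn) — reproduces the K114N missense call
on both splice isoforms.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .effect_annot import TranscriptModel

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("bsamap.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["log2fc"] = df["log2fc"].astype(float)
    df["q"] = df["q"].astype(float)
    return df


def load_cuticle_cellwall_degs() -> pd.DataFrame:
    """Curated cuticle / cell-wall DEG table (gene, function, category, log2FC, q)."""
    return _load_table("cuticle_cellwall_degs.tsv")


def load_hormone_degs() -> pd.DataFrame:
    """Curated hormone-associated DEG table (gene, function, category, log2FC, q)."""
    return _load_table("hormone_degs.tsv")


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_CHROM = "ch12_toy"
_CHROM_LEN = 1500
# X1 isoform: three exons; CDS = 220 aa + stop (663 nt)
_X1_EXONS = ((101, 370), (571, 692), (893, 1263))
_X1_CDS = ((151, 370), (571, 692), (893, 1213))
# X2 isoform: shares exons 1-2, shorter third coding exon (155 aa, no
# annotated stop — a deliberately partial isoform model)
_X2_EXONS = ((101, 370), (571, 692), (893, 1043))
_X2_CDS = ((151, 370), (571, 692), (893, 1018))
_CAUSAL = (_CHROM, 692, "G", "T")  # last base of exon 2 == codon 114 wobble-2 base


def synthetic_shn2_locus(strand: str = "+"):
    """Build the synthetic SHN2-like locus fixture.

    Returns ``(genome, transcripts, causal)`` where ``genome`` maps the toy
    chromosome name to its sequence, ``transcripts`` holds the two isoform
    models, and ``causal`` is the (chrom, pos, ref, alt) missense variant.
    ``strand="-"`` returns the mirror-image fixture (sequence
    reverse-complemented, coordinates reflected) for strand-symmetry checks.
    """
    rng = np.random.default_rng(43897)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=_CHROM_LEN))
    # coding sequence: 220 sense codons + TAA, with codon 114 fixed to AAG
    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), 220)]
    codons[113] = "AAG"
    cds_seq = "".join(codons) + "TAA"
    i = 0
    for s, e in _X1_CDS:
        for p in range(s, e + 1):
            seq[p - 1] = cds_seq[i]
            i += 1
    genome = {_CHROM: "".join(seq)}
    transcripts = [
        TranscriptModel("SHN2like.X1", "SHN2like", _CHROM, "+", _X1_EXONS, _X1_CDS),
        TranscriptModel("SHN2like.X2", "SHN2like", _CHROM, "+", _X2_EXONS, _X2_CDS),
    ]
    causal = _CAUSAL
    if strand == "-":
        return _mirror(genome, transcripts, causal)
    if strand != "+":
        raise ValueError("strand must be '+' or '-'")
    return genome, transcripts, causal


def _mirror(genome, transcripts, causal):
    chrom = causal[0]
    L = len(genome[chrom])
    rc = genome[chrom].translate(_COMPLEMENT)[::-1]
    flip = lambda iv: (L + 1 - iv[1], L + 1 - iv[0])
    mirrored = [
        TranscriptModel(
            t.transcript_id,
            t.gene_id,
            t.chrom,
            "-",
            tuple(sorted(flip(iv) for iv in t.exons)),
            tuple(sorted(flip(iv) for iv in t.cds)),
        )
        for t in transcripts
    ]
    c_pos = L + 1 - causal[1]
    c_ref = causal[2].translate(_COMPLEMENT)
    c_alt = causal[3].translate(_COMPLEMENT)
    return {chrom: rc}, mirrored, (chrom, c_pos, c_ref, c_alt)


def write_locus_fasta(genome: dict, path: str) -> None:
    """Write the fixture genome as FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_locus_gff3(transcripts, path: str) -> None:
    """Write transcript models as GFF3 (gene/mRNA/exon/CDS with phases)."""
    lines = ["##gff-version 3"]
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, []).append(t)
    for gene_id, ts in genes.items():
        g_start = min(t.span[0] for t in ts)
        g_end = max(t.span[1] for t in ts)
        chrom, strand = ts[0].chrom, ts[0].strand
        lines.append(
            f"{chrom}\tbsamap\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gene_id}"
        )
        for t in ts:
            lines.append(
                f"{chrom}\tbsamap\tmRNA\t{t.span[0]}\t{t.span[1]}\t.\t{strand}\t.\t"
                f"ID={t.transcript_id};Parent={gene_id}"
            )
            for s, e in t.exons:
                lines.append(
                    f"{chrom}\tbsamap\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"Parent={t.transcript_id}"
                )
            cds = list(t.cds) if strand == "+" else list(t.cds)[::-1]
            phase = 0
            for s, e in cds:
                lines.append(
                    f"{chrom}\tbsamap\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\t"
                    f"Parent={t.transcript_id}"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
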