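"""Transcriptome assembly from annotated ORFs and UTRs.

Builds per-transcript models by supplementing short or missing UTRs with
1000 nt flanking sequence, repairing ORFs whose length is not a whole
number of codons, and appending a stop codon where one is missing.  Also
computes the per-gene effective mappable length used as the ``L`` term of
RPKM: the number of distinct 30 nt windows across all of a gene's
transcripts, which corrects for sequence shared among isoforms.

Coordinates are 0-based, half-open throughout.  The annotation table on
disk stores UTR/ORF lengths (see :func:`read_annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

FLANK_LEN = 1000
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
#: Appended deterministically when an ORF lacks a stop codon.
DEFAULT_STOP = "TAA"

_VALID = frozenset("ACGTN")

# amino acid -> synonymous codons, from the standard genetic code
_SYNONYMOUS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _SYNONYMOUS.setdefault(_aa, []).append(_codon)


@dataclass
class TranscriptRecord:
    """Raw annotation input for one transcript.

    ``utr5_seq``/``utr3_seq`` may be ``None`` when unannotated;
    ``ref_protein`` is the reference protein used to resolve partial
    trailing codons, if available.
    """

    transcript_id: str
    gene_id: str
    orf_seq: str
    utr5_seq: str | None = None
    utr3_seq: str | None = None
    flank5_seq: str = ""
    flank3_seq: str = ""
    ref_protein: str | None = None


@dataclass
class TranscriptModel:
    """Assembled transcript: full sequence plus ORF offsets (0-based, half-open)."""

    transcript_id: str
    gene_id: str
    full_seq: str
    orf_start: int
    orf_end: int

    @property
    def orf_seq(self) -> str:
        return self.full_seq[self.orf_start : self.orf_end]

    def __len__(self) -> int:
        return len(self.full_seq)


@dataclass
class GeneModel:
    """A gene with its transcripts and effective mappable length ``L``."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    effective_len: int | None = None


def complete_partial_codon(orf_seq: str, ref_protein: str | None) -> str:
    """Repair an ORF whose length is not divisible by 3.

    The trailing 1-2 nt are interpreted as a partial codon for the amino
    acid at the position immediately following the whole-codon prefix of
    ``ref_protein``.  If exactly one synonymous codon of that amino acid
    is consistent with the partial codon, the codon is completed; if
    several are, the codon is padded with ``N``; if the reference protein
    has no residue at that position (or is absent), the ORF is truncated
    to whole codons.

    ORFs already a whole number of codons, and ORFs starting with one or
    two ``N`` characters, are returned unchanged.
    """
    rem = len(orf_seq) % 3
    if rem == 0:
        return orf_seq
    # leading-N guard: such ORFs are passed through unmodified
    lead = len(orf_seq) - len(orf_seq.lstrip("N"))
    if lead in (1, 2):
        return orf_seq

    prefix = orf_seq[: len(orf_seq) - rem]
    partial = orf_seq[len(orf_seq) - rem :]
    aa_pos = len(prefix) // 3

    if ref_protein is None or aa_pos >= len(ref_protein):
        return prefix  # truncate to whole codons

    aa = ref_protein[aa_pos].upper()
    candidates = [c for c in _SYNONYMOUS.get(aa, []) if c.startswith(partial)]
    if len(candidates) == 1:
        return prefix + candidates[0]
    return orf_seq + "N" * (3 - rem)


def assemble_transcript(rec: TranscriptRecord, min_utr_len: int = 4) -> TranscriptModel:
    """Assemble ``utr5 + repaired ORF + utr3`` into a :class:`TranscriptModel`.

    UTRs that are missing or shorter than ``min_utr_len`` are replaced by
    the corresponding 1000 nt flank.  The ORF is repaired with
    :func:`complete_partial_codon` and a stop codon (``TAA``) is appended
    when the final whole codon is not a stop.
    """
    if not rec.orf_seq:
        raise ValueError(f"{rec.transcript_id}: empty ORF")
    bad = set(rec.orf_seq.upper()) - _VALID
    if bad:
        raise ValueError(f"{rec.transcript_id}: ORF has invalid characters {sorted(bad)}")

    u5 = rec.utr5_seq if rec.utr5_seq and len(rec.utr5_seq) >= min_utr_len else rec.flank5_seq
    u3 = rec.utr3_seq if rec.utr3_seq and len(rec.utr3_seq) >= min_utr_len else rec.flank3_seq

    orf = complete_partial_codon(rec.orf_seq.upper(), rec.ref_protein)
    last = orf[-3:] if len(orf) >= 3 and len(orf) % 3 == 0 else ""
    if last not in STOP_CODONS and "N" not in last:
        orf = orf + DEFAULT_STOP

    full = (u5 or "") + orf + (u3 or "")
    start = len(u5 or "")
    return TranscriptModel(rec.transcript_id, rec.gene_id, full, start, start + len(orf))


def translate_orf(orf_seq: str) -> str:
    """Translate whole codons of an ORF (trailing partial codon ignored)."""
    n = len(orf_seq) - len(orf_seq) % 3
    return str(Seq(orf_seq[:n]).translate())


def effective_length(gene: GeneModel, k: int = 30) -> int:
    """Number of distinct ``k``-mers across the gene's transcript sequences.

    Transcripts shorter than ``k`` contribute nothing.  Raises
    ``ValueError`` when every transcript is shorter than ``k`` (the gene
    is unquantifiable).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kmers: set[str] = set()
    for t in gene.transcripts:
        s = t.full_seq
        for i in range(len(s) - k + 1):
            kmers.add(s[i : i + k])
    if not kmers:
        raise ValueError(f"{gene.gene_id}: all transcripts shorter than k={k}; unquantifiable")
    return len(kmers)


def build_gene_models(
    models: list[TranscriptModel], k: int = 30
) -> dict[str, GeneModel]:
    """Group transcript models by gene and compute effective lengths.

    Genes whose transcripts are all shorter than ``k`` get
    ``effective_len=None`` and are flagged unquantifiable downstream.
    """
    genes: dict[str, GeneModel] = {}
    for m in models:
        genes.setdefault(m.gene_id, GeneModel(m.gene_id)).transcripts.append(m)
    for g in genes.values():
        try:
            g.effective_len = effective_length(g, k=k)
        except ValueError:
            g.effective_len = None
    return genes


# ---------------------------------------------------------------------------
# on-disk interchange


def read_annotation(annot_path, fasta_path) -> list[TranscriptRecord]:
    """Load transcript records from an annotation TSV plus component FASTA.

    The FASTA holds, per transcript ``tid``, a record ``tid`` with the
    concatenated ``utr5+orf+utr3`` sequence and records ``tid|flank5`` /
    ``tid|flank3`` with the 1000 nt flanks.  The TSV columns
    ``utr5_len/orf_len/utr3_len`` give the split points; ``ref_protein``
    is a sequence or ``-``.
    """
    from Bio import SeqIO

    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    tab = pd.read_csv(annot_path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    records = []
    for row in tab.itertuples(index=False):
        body = seqs[row.transcript_id]
        u5, orf_len = int(row.utr5_len), int(row.orf_len)
        records.append(
            TranscriptRecord(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                utr5_seq=body[:u5] or None,
                orf_seq=body[u5 : u5 + orf_len],
                utr3_seq=body[u5 + orf_len :] or None,
                flank5_seq=seqs.get(f"{row.transcript_id}|flank5", ""),
                flank3_seq=seqs.get(f"{row.transcript_id}|flank3", ""),
                ref_protein=None if row.ref_protein in ("-", "", None) else str(row.ref_protein),
            )
        )
    return records


def build_transcriptome(annot_path, fasta_path, k: int = 30):
    """Read annotation + FASTA and return (transcript models, gene models)."""
    records = read_annotation(annot_path, fasta_path)
    models = [assemble_transcript(r) for r in records]
    return models, build_gene_models(models, k=k)
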