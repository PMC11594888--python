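"""Functional classification of SNPs against gene models.

Categories (mutually exclusive, by precedence):
Exonic > Splicing > Intronic > Upstream/Downstream > Upstream > Downstream >
Intergenic.  Exonic SNPs carry a coding consequence (Synonymous,
Non-synonymous, Stop gain, Stop loss).  Flanks are strand-aware 1 kb beyond
the transcript span; splice sites are intronic positions within 2 bp of an
exon/intron boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

CATEGORIES = [
    "Exonic",
    "Splicing",
    "Intronic",
    "Upstream/Downstream",
    "Upstream",
    "Downstream",
    "Intergenic",
]

EXONIC_SUBCATEGORIES = ["Stop gain", "Stop loss", "Non-synonymous", "Synonymous"]

FLANK_BP = 1000
SPLICE_BP = 2

_SUBCAT_SEVERITY = {s: i for i, s in enumerate(EXONIC_SUBCATEGORIES)}


@dataclass
class GeneModel:
    """A stranded transcript: overall span, exons and CDS (1-based inclusive).

    Exons must be sorted and non-overlapping; CDS intervals must lie inside
    exons.  A gene may contribute several GeneModels (one per transcript).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)


@dataclass
class AnnotatedVariant:
    key: tuple[str, int]  # (chrom, pos)
    category: str
    exonic_subcategory: str | None = None
    genes: list[str] = field(default_factory=list)


def classify_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    models: list[GeneModel],
    reference: dict[str, str],
) -> AnnotatedVariant:
    """Assign the single functional category of a SNP.

    ``reference`` maps chromosome name to its full sequence (1-based access
    via ``seq[pos-1]``); the base at ``pos`` must equal ``ref``.
    """
    seq = reference.get(chrom)
    if seq is not None and seq[pos - 1].upper() != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {ref}, "
            f"found {seq[pos - 1]}"
        )

    exonic_sub: str | None = None
    exonic_genes: list[str] = []
    splicing_genes: list[str] = []
    intronic_genes: list[str] = []
    upstream_genes: list[str] = []
    downstream_genes: list[str] = []

    for m in models:
        if m.chrom != chrom:
            continue
        if m.start <= pos <= m.end:
            in_cds = any(a <= pos <= b for a, b in m.cds)
            if in_cds:
                sub = coding_consequence(pos, ref, alt, m, reference)
                if exonic_sub is None or _SUBCAT_SEVERITY[sub] < _SUBCAT_SEVERITY[exonic_sub]:
                    exonic_sub = sub
                exonic_genes.append(m.gene_id)
            elif _is_splice_site(pos, m):
                splicing_genes.append(m.gene_id)
            else:
                intronic_genes.append(m.gene_id)
        else:
            # strand-aware 1 kb flanks beyond the transcript span
            if m.strand == "+":
                up = (m.start - FLANK_BP, m.start - 1)
                down = (m.end + 1, m.end + FLANK_BP)
            else:
                up = (m.end + 1, m.end + FLANK_BP)
                down = (m.start - FLANK_BP, m.start - 1)
            if up[0] <= pos <= up[1]:
                upstream_genes.append(m.gene_id)
            elif down[0] <= pos <= down[1]:
                downstream_genes.append(m.gene_id)

    key = (chrom, pos)
    if exonic_genes:
        return AnnotatedVariant(key, "Exonic", exonic_sub, _dedup(exonic_genes))
    if splicing_genes:
        return AnnotatedVariant(key, "Splicing", None, _dedup(splicing_genes))
    if intronic_genes:
        return AnnotatedVariant(key, "Intronic", None, _dedup(intronic_genes))
    if upstream_genes and downstream_genes:
        return AnnotatedVariant(
            key, "Upstream/Downstream", None, _dedup(upstream_genes + downstream_genes)
        )
    if upstream_genes:
        return AnnotatedVariant(key, "Upstream", None, _dedup(upstream_genes))
    if downstream_genes:
        return AnnotatedVariant(key, "Downstream", None, _dedup(downstream_genes))
    return AnnotatedVariant(key, "Intergenic", None, [])


def _dedup(items: list[str]) -> list[str]:
    return list(dict.fromkeys(items))


def _is_splice_site(pos: int, m: GeneModel) -> bool:
    """Intronic position within SPLICE_BP of an internal exon/intron boundary."""
    if any(a <= pos <= b for a, b in m.exons):
        return False
    for (a1, b1), (a2, b2) in zip(m.exons, m.exons[1:]):
        if b1 < pos < a2 and (pos - b1 <= SPLICE_BP or a2 - pos <= SPLICE_BP):
            return True
    return False


def coding_consequence(
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel,
    reference: dict[str, str],
) -> str:
    """Coding consequence of a SNP inside the CDS of ``model``.

    The codon is rebuilt in transcript orientation (reverse complement on the
    minus strand) and translated with the standard genetic code.  Stop
    gain/loss take precedence over synonymous/non-synonymous.
    """
    seq = reference[model.chrom]
    # CDS sequence in genome order, tracking the position of the SNP
    cds_seq = []
    snp_offset = None
    for a, b in model.cds:
        if a <= pos <= b:
            snp_offset = len(cds_seq) + (pos - a)
        cds_seq.append(seq[a - 1 : b])
    if snp_offset is None:
        raise ValueError(f"position {pos} is not inside the CDS of {model.gene_id}")
    cds_ref = "".join(cds_seq).upper()
    if model.cds_length % 3 != 0:
        warnings.warn(
            f"CDS length of {model.gene_id} not divisible by 3; classifying "
            "by available codon",
            stacklevel=2,
        )
    cds_alt = cds_ref[:snp_offset] + alt.upper() + cds_ref[snp_offset + 1 :]
    if model.strand == "-":
        cds_ref = str(Seq(cds_ref).reverse_complement())
        cds_alt = str(Seq(cds_alt).reverse_complement())
        snp_offset = len(cds_ref) - 1 - snp_offset
    codon_i = snp_offset // 3
    codon_ref = cds_ref[codon_i * 3 : codon_i * 3 + 3]
    codon_alt = cds_alt[codon_i * 3 : codon_i * 3 + 3]
    if len(codon_ref) < 3:
        return "Synonymous"  # trailing partial codon, cannot translate
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_ref != "*" and aa_alt == "*":
        return "Stop gain"
    if aa_ref == "*" and aa_alt != "*":
        return "Stop loss"
    return "Synonymous" if aa_ref == aa_alt else "Non-synonymous"


def summarize_annotations(
    annotations: list[AnnotatedVariant], total: int
) -> pd.DataFrame:
    """Category counts and percentages (100 x count/total, 2 d.p.).

    ``total`` is taken explicitly: printed component counts need not sum to
    the denominator used for percentages.
    """
    if total == 0:
        raise ValueError("total must be positive")
    if total < len(annotations):
        raise ValueError("total smaller than number of annotated variants")
    counts: dict[str, int] = {}
    for a in annotations:
        if a.category == "Exonic":
            counts["Exonic"] = counts.get("Exonic", 0) + 1
            counts[a.exonic_subcategory] = counts.get(a.exonic_subcategory, 0) + 1
        else:
            counts[a.category] = counts.get(a.category, 0) + 1
    return summarize_counts(counts, total)


def summarize_counts(counts: dict[str, int], total: int) -> pd.DataFrame:
    """Summary table from pre-tabulated category counts (same rounding)."""
    if total == 0:
        raise ValueError("total must be positive")
    order = [
        "Upstream",
        "Exonic",
        "Stop gain",
        "Stop loss",
        "Synonymous",
        "Non-synonymous",
        "Intronic",
        "Splicing",
        "Downstream",
        "Upstream/Downstream",
        "Intergenic",
    ]
    rows = []
    for cat in order:
        if cat in counts:
            c = counts[cat]
            rows.append((cat, c, round(100.0 * c / total, 2)))
    for cat, c in counts.items():
        if cat not in order:
            rows.append((cat, c, round(100.0 * c / total, 2)))
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def read_gff3(path: str) -> list[GeneModel]:
    """Parse gene models from a GFF3 file.

    Builds one GeneModel per mRNA (or per gene when no mRNA children exist),
    using exon and CDS features linked by the Parent attribute.
    """
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            feats.append(
                dict(
                    chrom=chrom,
                    type=ftype,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    id=attr.get("ID"),
                    parent=attr.get("Parent"),
                )
            )

    gene_of: dict[str, str] = {}  # transcript id -> gene id
    transcripts: dict[str, dict] = {}
    for f in feats:
        if f["type"] in ("mRNA", "transcript"):
            tid = f["id"]
            transcripts[tid] = dict(
                chrom=f["chrom"],
                strand=f["strand"],
                start=f["start"],
                end=f["end"],
                exons=[],
                cds=[],
            )
            gene_of[tid] = f["parent"] or tid
    for f in feats:
        if f["type"] in ("exon", "CDS") and f["parent"] in transcripts:
            key = "exons" if f["type"] == "exon" else "cds"
            transcripts[f["parent"]][key].append((f["start"], f["end"]))

    models = []
    for tid, t in transcripts.items():
        models.append(
            GeneModel(
                gene_id=gene_of[tid],
                chrom=t["chrom"],
                strand=t["strand"],
                start=t["start"],
                end=t["end"],
                exons=t["exons"] or [(t["start"], t["end"])],
                cds=t["cds"],
            )
        )
    return models


def write_gff3(models: list[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (gene + mRNA + exon + CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            base = f"{m.chrom}\tpopsweep\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(
                base + f"gene\t{m.start}\t{m.end}" + tail + f".\tID=gene:{m.gene_id}\n"
            )
            tid = f"{m.gene_id}.t1"
            fh.write(
                base
                + f"mRNA\t{m.start}\t{m.end}"
                + tail
                + f".\tID={tid};Parent={m.gene_id}\n"
            )
            for a, b in m.exons:
                fh.write(base + f"exon\t{a}\t{b}" + tail + f".\tParent={tid}\n")
            phase = 0
            cds = m.cds if m.strand == "+" else list(reversed(m.cds))
            for a, b in cds:
                fh.write(base + f"CDS\t{a}\t{b}" + tail + f"{phase}\tParent={tid}\n")
                phase = (3 - ((b - a + 1 - phase) % 3)) % 3


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into a chrom -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def annotate_matrix(g, models: list[GeneModel], reference: dict[str, str]):
    """Classify every variant of a GenotypeMatrix; returns list of AnnotatedVariant."""
    out = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for v in g.variants.itertuples(index=False):
        out.append(
            classify_variant(
                v.chrom, int(v.pos), v.ref, v.alt, by_chrom.get(v.chrom, []), reference
            )
        )
    return out
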