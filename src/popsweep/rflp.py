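"""In-silico PCR-RFLP design: does a SNP create or destroy a restriction
site, and what fragment pattern does each genotype produce on a gel?

Motifs may contain IUPAC ambiguity codes.  Scanning is forward-strand by
default (typical RFLP motifs are palindromic); reverse-strand scanning for
non-palindromic motifs is available behind a flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

_IUPAC_RE = {
    code: (vals if len(vals) == 1 else f"[{vals}]")
    for code, vals in ambiguous_dna_values.items()
}


@dataclass
class Amplicon:
    """A PCR product carrying one SNP at a known offset."""

    name: str
    sequence: str
    snp_offset: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not 0 <= self.snp_offset < len(self.sequence):
            raise ValueError("SNP offset outside amplicon")
        if self.sequence[self.snp_offset] != self.ref.upper():
            raise ValueError(
                f"amplicon base {self.sequence[self.snp_offset]} at offset "
                f"{self.snp_offset} does not match ref allele {self.ref}"
            )


@dataclass
class Enzyme:
    name: str
    motif: str  # IUPAC codes allowed
    cut_offset: int  # cut position within the motif, 0..len(motif)

    def __post_init__(self) -> None:
        self.motif = self.motif.upper()
        if len(self.motif) < 4:
            raise ValueError(f"motif of {self.name} shorter than 4 bp")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError(f"cut offset of {self.name} outside motif")
        for base in self.motif:
            if base not in _IUPAC_RE:
                raise ValueError(f"invalid IUPAC code {base!r} in {self.name}")

    @property
    def is_palindromic(self) -> bool:
        return self.motif == str(Seq(self.motif).reverse_complement())

    def pattern(self) -> re.Pattern:
        return re.compile("".join(_IUPAC_RE[b] for b in self.motif))


def find_sites(seq: str, enzyme: Enzyme, scan_reverse: bool = False) -> list[int]:
    """Cut positions (0-based, cut before the returned index) of all motif
    matches on the forward strand; optionally also the reverse strand for
    non-palindromic motifs."""
    seq = seq.upper()
    for base in seq:
        if base not in "ACGT":
            raise ValueError(f"invalid nucleotide {base!r}")
    pat = enzyme.pattern()
    cuts = []
    for i in range(len(seq) - len(enzyme.motif) + 1):
        if pat.match(seq, i):
            cuts.append(i + enzyme.cut_offset)
    if scan_reverse and not enzyme.is_palindromic:
        rc_motif = str(Seq(enzyme.motif).reverse_complement())
        rc_pat = re.compile("".join(_IUPAC_RE[b] for b in rc_motif))
        L = len(enzyme.motif)
        for i in range(len(seq) - L + 1):
            if rc_pat.match(seq, i):
                # cut on the bottom strand, reported in top-strand coordinates
                cuts.append(i + L - enzyme.cut_offset)
    return sorted(set(cuts))


def fragment_pattern(
    amp: Amplicon, enzyme: Enzyme, allele: str, scan_reverse: bool = False
) -> list[int]:
    """Digestion fragment lengths (descending) of the amplicon carrying
    ``allele`` at the SNP position."""
    allele = allele.upper()
    if allele not in (amp.ref.upper(), amp.alt.upper()):
        raise ValueError(f"allele {allele!r} is neither ref nor alt")
    seq = amp.sequence[: amp.snp_offset] + allele + amp.sequence[amp.snp_offset + 1 :]
    cuts = [c for c in find_sites(seq, enzyme, scan_reverse) if 0 < c < len(seq)]
    bounds = [0] + cuts + [len(seq)]
    frags = [b - a for a, b in zip(bounds, bounds[1:])]
    return sorted(frags, reverse=True)


def genotype_patterns(
    amp: Amplicon, enzyme: Enzyme, scan_reverse: bool = False
) -> dict[str, list[int]]:
    """Fragment pattern per genotype; the heterozygote is the multiset union
    of the two homozygote digests (gel-band interpretation)."""
    ref_pat = fragment_pattern(amp, enzyme, amp.ref, scan_reverse)
    alt_pat = fragment_pattern(amp, enzyme, amp.alt, scan_reverse)
    het = sorted(ref_pat + alt_pat, reverse=True)
    return {"hom_ref": ref_pat, "het": het, "hom_alt": alt_pat}


def snp_alters_site(
    amp: Amplicon, enzymes: list[Enzyme], scan_reverse: bool = False
) -> list[Enzyme]:
    """Enzymes whose cut count differs between the two alleles, i.e. usable
    for RFLP genotyping of this SNP."""
    usable = []
    ref_seq = amp.sequence
    alt_seq = (
        amp.sequence[: amp.snp_offset] + amp.alt.upper() + amp.sequence[amp.snp_offset + 1 :]
    )
    for enz in enzymes:
        ref_cuts = find_sites(ref_seq, enz, scan_reverse)
        alt_cuts = find_sites(alt_seq, enz, scan_reverse)
        if ref_cuts != alt_cuts:
            usable.append(enz)
    return usable


def read_enzymes(path: str) -> list[Enzyme]:
    """Load an enzyme table TSV with columns name, motif, cut_offset."""
    df = pd.read_csv(path, sep="\t")
    return [
        Enzyme(name=r["name"], motif=r["motif"], cut_offset=int(r["cut_offset"]))
        for _, r in df.iterrows()
    ]


def design_report(
    amplicons: list[Amplicon], enzymes: list[Enzyme], scan_reverse: bool = False
) -> pd.DataFrame:
    """Per (amplicon, usable enzyme) fragment patterns for the three
    genotypes; amplicons with no usable enzyme get a flagged row."""
    rows = []
    for amp in amplicons:
        usable = snp_alters_site(amp, enzymes, scan_reverse)
        if not usable:
            rows.append(
                dict(
                    amplicon=amp.name,
                    enzyme=None,
                    usable=False,
                    hom_ref="",
                    het="",
                    hom_alt="",
                )
            )
            continue
        for enz in usable:
            pats = genotype_patterns(amp, enz, scan_reverse)
            rows.append(
                dict(
                    amplicon=amp.name,
                    enzyme=enz.name,
                    usable=True,
                    hom_ref=",".join(map(str, pats["hom_ref"])),
                    het=",".join(map(str, pats["het"])),
                    hom_alt=",".join(map(str, pats["hom_alt"])),
                )
            )
    return pd.DataFrame(rows)
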