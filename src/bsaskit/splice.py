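"""Splice-variant comparison and virtual RT-PCR sex-typing.

Transcript variants are compared against a reference gene model by
coordinate-interval arithmetic (exon skipping, 5'/3' exon shortening,
novel exons, intron retention), and end-point RT-PCR assays are predicted
in silico by primer matching on transcript sequences.  The motivating use
case is the pair of gonadal sex assays in which a DM-domain amplicon is
testis-specific and an aromatase exon-1 3'-boundary amplicon is
ovary-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panel import PrimerPair, reverse_complement, strip_overhang


class SpliceError(ValueError):
    pass


@dataclass
class GeneModel:
    """Reference exon chain of a gene in 1-based inclusive gene coordinates.

    ``annotated_domains`` are named intervals in *reference transcript*
    coordinates (e.g. the DM domain of a dmrt-family gene).
    """

    gene: str
    exons: list[tuple[str, int, int]]
    genomic_sequence: str | None = None
    annotated_domains: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = 0
        for name, s, e in self.exons:
            if s > e:
                raise SpliceError(f"{self.gene} exon {name}: start {s} > end {e}")
            if s <= prev_end:
                raise SpliceError(f"{self.gene} exons overlap or are unsorted at {name}")
            prev_end = e

    def transcript_length(self) -> int:
        return sum(e - s + 1 for _, s, e in self.exons)

    def spliced_sequence(self) -> str:
        if self.genomic_sequence is None:
            raise SpliceError(f"{self.gene}: no genomic sequence attached")
        return "".join(self.genomic_sequence[s - 1 : e] for _, s, e in self.exons)

    def domain_genomic_bases(self, domain_name: str) -> set[int]:
        """Genomic positions underlying a transcript-coordinate domain."""
        for name, (d1, d2) in self.annotated_domains:
            if name == domain_name:
                break
        else:
            raise KeyError(domain_name)
        bases: set[int] = set()
        t = 0
        for _, s, e in self.exons:
            for g in range(s, e + 1):
                t += 1
                if d1 <= t <= d2:
                    bases.add(g)
        if len(bases) != d2 - d1 + 1:
            raise SpliceError(
                f"domain {domain_name} extends past the reference transcript"
            )
        return bases


@dataclass
class Isoform:
    """A transcript variant as an exon chain in gene coordinates."""

    transcript_id: str
    exon_chain: list[tuple[int, int]]
    sequence: str | None = None

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.exon_chain:
            if s > e:
                raise SpliceError(f"{self.transcript_id}: segment start {s} > end {e}")
            if s <= prev_end:
                raise SpliceError(f"{self.transcript_id}: exon chain unsorted/overlapping")
            prev_end = e
        if self.sequence is not None:
            expect = sum(e - s + 1 for s, e in self.exon_chain)
            if len(self.sequence) != expect:
                raise SpliceError(
                    f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                    f"exon-chain length {expect}"
                )

    def splice_from(self, genomic: str) -> str:
        return "".join(genomic[s - 1 : e] for s, e in self.exon_chain)

    def covered_bases(self) -> set[int]:
        return {g for s, e in self.exon_chain for g in range(s, e + 1)}


@dataclass(frozen=True)
class SpliceEvent:
    """One difference between an isoform and the reference exon structure.

    ``delta`` is the signed base count: negative for removed sequence
    (skipping, shortening), positive for gained sequence (novel exon,
    intron retention).
    """

    kind: str
    exon_ref: str
    delta: int

    _KINDS = frozenset(
        {"exon_skipped", "exon_shortened_5p", "exon_shortened_3p", "novel_exon",
         "intron_retained"}
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise SpliceError(f"unknown splice-event kind {self.kind!r}")
        if self.kind in {"exon_shortened_5p", "exon_shortened_3p", "novel_exon"}:
            if self.delta == 0:
                raise SpliceError(f"{self.kind} requires a non-zero delta")


def exon_diff(isoform: Isoform, model: GeneModel) -> list[SpliceEvent]:
    """Classify structural differences between an isoform and a gene model.

    Per reference exon: no overlapping isoform segment -> exon_skipped;
    a segment truncated at the 5' or 3' boundary -> exon_shortened with
    the (negative) number of bases lost; a segment extending past an exon
    boundary -> intron_retained.  Isoform segments overlapping no
    reference exon are novel exons.  Events are reported 5' to 3'.
    """
    events: list[tuple[int, SpliceEvent]] = []
    chain = isoform.exon_chain
    matched_segments: set[int] = set()
    for name, es, ee in model.exons:
        overlaps = [
            (k, (s, e)) for k, (s, e) in enumerate(chain) if s <= ee and e >= es
        ]
        if not overlaps:
            events.append((es, SpliceEvent("exon_skipped", name, -(ee - es + 1))))
            continue
        for k, (s, e) in overlaps:
            matched_segments.add(k)
            if s > es:
                events.append((es, SpliceEvent("exon_shortened_5p", name, -(s - es))))
            elif s < es:
                events.append((s, SpliceEvent("intron_retained", name, es - s)))
            if e < ee:
                events.append((e, SpliceEvent("exon_shortened_3p", name, -(ee - e))))
            elif e > ee:
                events.append((ee, SpliceEvent("intron_retained", name, e - ee)))
    for k, (s, e) in enumerate(chain):
        if k not in matched_segments:
            events.append((s, SpliceEvent("novel_exon", f"segment@{s}", e - s + 1)))
    events.sort(key=lambda t: t[0])
    return [ev for _, ev in events]


def domain_present(isoform: Isoform, model: GeneModel, domain_name: str) -> bool:
    """Whether a transcript-coordinate domain survives in the isoform.

    True iff every genomic base underlying the domain interval of the
    reference transcript is covered by the isoform's exon chain; removing
    exons can therefore never turn an absent domain present.
    """
    return model.domain_genomic_bases(domain_name) <= isoform.covered_bases()


@dataclass(frozen=True)
class PcrProduct:
    start: int  # 1-based sense position of the forward primer 5' base
    end: int    # 1-based sense position of the reverse-primer footprint 3'-most base
    length: int


@dataclass(frozen=True)
class VirtualPcrResult:
    products: tuple[PcrProduct, ...]

    @property
    def product(self) -> int | None:
        """Single product length, or None when absent/non-specific."""
        return self.products[0].length if len(self.products) == 1 else None

    @property
    def specific(self) -> bool:
        return len(self.products) == 1

    @property
    def positive(self) -> bool:
        return len(self.products) > 0


def _match_sites(primer: str, seq: str, max_mismatch: int, exact_3p_index: int) -> list[int]:
    """Start offsets where primer matches seq, requiring an exact base at
    the primer's 3'-terminal position (index within the footprint)."""
    n = len(primer)
    sites = []
    for off in range(len(seq) - n + 1):
        window = seq[off : off + n]
        if window[exact_3p_index] != primer[exact_3p_index]:
            continue
        mism = sum(a != b for a, b in zip(window, primer))
        if mism <= max_mismatch:
            sites.append(off)
    return sites


def virtual_pcr(
    primers: PrimerPair, transcript: str, max_mismatch: int = 0
) -> VirtualPcrResult:
    """Predict end-point PCR products on a transcript.

    The forward primer is searched on the sense strand and the reverse
    primer on the antisense strand, each requiring a perfect 3'-terminal
    base (polymerase extension cannot start from a mismatched 3' end).
    Product sizes are inclusive of both primer footprints, as gel sizes
    are reported.  Multiple candidate products are all returned and the
    result flagged non-specific.
    """
    t = transcript.upper()
    fwd = strip_overhang(primers.seq_fwd)[0]
    rev = strip_overhang(primers.seq_rev)[0]
    if not fwd or not rev:
        raise SpliceError("empty primer")
    fwd_sites = _match_sites(fwd, t, max_mismatch, len(fwd) - 1)
    # On the sense strand the reverse primer footprint reads as revcomp(rev);
    # the primer's 3'-terminal base maps to the footprint's leftmost base.
    rc = reverse_complement(rev)
    rev_sites = _match_sites(rc, t, max_mismatch, 0)
    products = []
    for i in fwd_sites:
        for j in rev_sites:
            if i <= j:  # forward footprint must start upstream of the reverse one
                end = j + len(rc)  # 1-based inclusive 3'-most footprint base
                products.append(PcrProduct(start=i + 1, end=end, length=end - i))
    return VirtualPcrResult(tuple(sorted(set(products), key=lambda p: (p.start, p.end))))


def sex_type(
    male_assay: VirtualPcrResult, female_assay: VirtualPcrResult
) -> str:
    """Combine the two sex-specific assays into a typing call.

    The male assay targets the DM-domain-bearing transcript, the female
    assay the full-length aromatase exon 1 boundary; a clean sample is
    positive for exactly one of them.
    """
    m, f = male_assay.positive, female_assay.positive
    if m and not f:
        return "male-pattern"
    if f and not m:
        return "female-pattern"
    return "both" if m else "neither"


def sex_type_transcripts(
    transcripts: list[str],
    male_primers: PrimerPair,
    female_primers: PrimerPair,
    max_mismatch: int = 0,
) -> str:
    """Sex-type a transcript set: each assay is positive if any transcript
    yields a product."""
    male = [virtual_pcr(male_primers, t, max_mismatch) for t in transcripts]
    female = [virtual_pcr(female_primers, t, max_mismatch) for t in transcripts]
    male_hit = next((r for r in male if r.positive), VirtualPcrResult(()))
    female_hit = next((r for r in female if r.positive), VirtualPcrResult(()))
    return sex_type(male_hit, female_hit)
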