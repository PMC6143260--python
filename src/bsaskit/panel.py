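"""Targeted bisulfite amplicon panel: coordinates, CpG sites, conversion, primers.

The panel targets proximal promoters and first exons of sex-related genes.
Coordinates are TSS-relative signed integers with no position zero
(..., -2, -1, +1, +2, ...).  Amplicon length is the *naive* signed
subtraction ``end - start``: that convention, and only that one, reproduces
every printed amplicon size of the source panel, including regions that
cross the TSS.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

import yaml

# Illumina Nextera-style adapter overhangs prepended to locus-specific cores.
FORWARD_OVERHANG = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
REVERSE_OVERHANG = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"

_DNA_RE = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InvalidPositionError(ValueError):
    """A TSS-relative coordinate of zero (the convention has no zero)."""


class PanelError(ValueError):
    """Inconsistent or incomplete amplicon panel definition."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_position(value: int) -> int:
    value = int(value)
    if value == 0:
        raise InvalidPositionError("TSS-relative coordinates have no position 0")
    return value


def amplicon_length(start: int, end: int) -> int:
    """Amplicon size in bp from TSS-relative endpoints.

    Plain signed subtraction ``end - start``; both endpoints must be
    non-zero and ``start < end``.
    """
    start, end = _check_position(start), _check_position(end)
    if start >= end:
        raise InvalidPositionError(f"start {start} must precede end {end}")
    return end - start


def index_to_pos(start: int, index: int) -> int:
    """TSS-relative position of the base at 0-based ``index`` of an amplicon."""
    start = _check_position(start)
    if index < 0:
        raise ValueError("index must be >= 0")
    pos = start + index
    if start < 0 <= pos:
        pos += 1  # skip the non-existent position 0
    return pos


def pos_to_index(start: int, pos: int) -> int:
    """0-based sequence index of TSS-relative ``pos`` in an amplicon at ``start``."""
    start, pos = _check_position(start), _check_position(pos)
    index = pos - start
    if start < 0 < pos:
        index -= 1
    if index < 0:
        raise ValueError(f"position {pos} precedes amplicon start {start}")
    return index


@dataclass(frozen=True)
class CpGSite:
    """A CpG dinucleotide, identified by the TSS-relative position of its C."""

    gene: str
    amplicon_id: str
    position: int

    def __post_init__(self) -> None:
        _check_position(self.position)


@dataclass(frozen=True)
class PrimerPair:
    """A bisulfite PCR primer pair; sequences may carry adapter overhangs."""

    name_fwd: str
    name_rev: str
    seq_fwd: str
    seq_rev: str
    overhang_fwd: str = FORWARD_OVERHANG
    overhang_rev: str = REVERSE_OVERHANG

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.seq_fwd), ("reverse", self.seq_rev)):
            if not seq or not _DNA_RE.match(seq):
                raise PanelError(f"{label} primer must be non-empty A/C/G/T: {seq!r}")
        for label, over, seq in (
            ("forward", self.overhang_fwd, self.seq_fwd),
            ("reverse", self.overhang_rev, self.seq_rev),
        ):
            if over and len(seq) > len(over) and seq.startswith(over[: len(seq)]):
                continue  # overhang present as prefix (or core-only primer)

    @property
    def core_fwd(self) -> str:
        return strip_overhang(self.seq_fwd)[0]

    @property
    def core_rev(self) -> str:
        return strip_overhang(self.seq_rev)[0]


def strip_overhang(primer: str) -> tuple[str, str | None]:
    """Remove an exact adapter-overhang prefix from a primer.

    Returns ``(core, which)`` with ``which`` one of ``"FO"``, ``"RO"`` or
    ``None``.  A primer without an overhang is returned unchanged.
    """
    if primer.startswith(FORWARD_OVERHANG):
        return primer[len(FORWARD_OVERHANG):], "FO"
    if primer.startswith(REVERSE_OVERHANG):
        return primer[len(REVERSE_OVERHANG):], "RO"
    return primer, None


def enumerate_cpg_sites(
    sequence: str, start: int, gene: str = "", amplicon_id: str = ""
) -> list[CpGSite]:
    """All CpG sites of a sequence, labeled by the TSS-relative C position.

    Scans every offset, so "CGCG" yields two sites; an empty sequence
    yields an empty list.
    """
    if not sequence:
        return []
    sequence = sequence.upper()
    if not re.fullmatch(r"[ACGTN]*", sequence):
        raise PanelError("sequence must contain only A/C/G/T/N")
    return [
        CpGSite(gene, amplicon_id, index_to_pos(start, i))
        for i in range(len(sequence) - 1)
        if sequence[i] == "C" and sequence[i + 1] == "G"
    ]


def bisulfite_convert(
    sequence: str,
    methylated_positions: Iterable[int] = (),
    strand: str = "top",
    start: int = 1,
) -> str:
    """In-silico bisulfite conversion of a sequence.

    Top strand: every C becomes T, except methylated CpG C's.  Bottom
    strand (written in top-strand coordinates): every G becomes A, except
    the G pairing a methylated CpG C.  ``methylated_positions`` are
    TSS-relative positions of CpG C's; the fully-converted call is the
    empty set.
    """
    meth = {int(p) for p in methylated_positions}
    seq = list(sequence.upper())
    meth_idx = set()
    for pos in meth:
        i = pos_to_index(start, pos)
        if i >= len(seq) or seq[i] != "C" or i + 1 >= len(seq) or seq[i + 1] != "G":
            raise PanelError(f"methylated position {pos} is not a CpG cytosine")
        meth_idx.add(i)
    if strand == "top":
        return "".join(
            "T" if b == "C" and i not in meth_idx else b for i, b in enumerate(seq)
        )
    if strand == "bottom":
        paired = {i + 1 for i in meth_idx}
        return "".join(
            "A" if b == "G" and i not in paired else b for i, b in enumerate(seq)
        )
    raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")


@dataclass
class Amplicon:
    """One targeted bisulfite PCR amplicon.

    ``sequence`` is the unconverted top strand and is optional: the panel
    is usable from declared coordinates and CpG counts alone, with
    concrete sequences synthesized on demand by the simulator.
    """

    gene: str
    amplicon_id: str
    start: int
    end: int
    primers: PrimerPair
    declared_length: int | None = None
    declared_cpg_count: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        length = amplicon_length(self.start, self.end)
        if self.declared_length is None:
            self.declared_length = length
        elif self.declared_length != length:
            raise PanelError(
                f"{self.amplicon_id}: declared length {self.declared_length} != "
                f"end - start = {length}"
            )
        if self.declared_cpg_count < 0:
            raise PanelError(f"{self.amplicon_id}: negative CpG count")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.declared_length:
                raise PanelError(
                    f"{self.amplicon_id}: sequence length {len(self.sequence)} != "
                    f"declared {self.declared_length}"
                )
            n_cpg = len(enumerate_cpg_sites(self.sequence, self.start))
            if n_cpg != self.declared_cpg_count:
                raise PanelError(
                    f"{self.amplicon_id}: sequence has {n_cpg} CpG, "
                    f"declared {self.declared_cpg_count}"
                )

    @property
    def length(self) -> int:
        return self.declared_length  # type: ignore[return-value]

    def cpg_sites(self) -> list[CpGSite]:
        if self.sequence is None:
            raise PanelError(f"{self.amplicon_id}: no sequence attached")
        return enumerate_cpg_sites(self.sequence, self.start, self.gene, self.amplicon_id)

    def cpg_indices(self) -> list[int]:
        """0-based sequence indices of CpG cytosines."""
        if self.sequence is None:
            raise PanelError(f"{self.amplicon_id}: no sequence attached")
        return [
            i
            for i in range(len(self.sequence) - 1)
            if self.sequence[i] == "C" and self.sequence[i + 1] == "G"
        ]

    def converted_sequence(self) -> str:
        """Fully bisulfite-converted top strand (no methylation retained)."""
        if self.sequence is None:
            raise PanelError(f"{self.amplicon_id}: no sequence attached")
        return bisulfite_convert(self.sequence, (), "top", self.start)


def cpg_density(amplicon: Amplicon) -> float:
    """CpG sites per 100 bp of amplicon."""
    if amplicon.length <= 0:
        raise PanelError(f"{amplicon.amplicon_id}: non-positive length")
    return 100.0 * amplicon.declared_cpg_count / amplicon.length


@dataclass(frozen=True)
class PrimerValidation:
    """Bisulfite-compatibility report for one primer pair."""

    fwd_has_no_c: bool
    rev_has_no_g: bool
    cores_have_no_cpg: bool
    fwd_matches_converted: bool | None = None
    rev_matches_converted: bool | None = None
    no_amplification_unconverted: bool | None = None

    @property
    def bisulfite_compatible(self) -> bool:
        return self.fwd_has_no_c and self.rev_has_no_g and self.cores_have_no_cpg


def _hamming_search(needle: str, haystack: str, max_mismatch: int) -> bool:
    n, h = len(needle), len(haystack)
    for off in range(h - n + 1):
        window = haystack[off : off + n]
        mism = sum(a != b for a, b in zip(needle, window))
        if mism <= max_mismatch:
            return True
    return False


def validate_bisulfite_primers(
    pp: PrimerPair, template: str | None = None, max_mismatch: int = 2
) -> PrimerValidation:
    """Check a primer pair against bisulfite PCR design rules.

    After converting the template, every original C on the top strand is a
    T, so a valid forward primer carries no C and a valid reverse primer
    (complementary strand) carries no G; neither core may span a CpG,
    whose state is unknown at design time.  With a template supplied, the
    cores must match the converted top strand / its reverse complement
    within ``max_mismatch`` substitutions, while at least one of them must
    *fail* to match the unconverted template (no amplification from
    genomic DNA).
    """
    fwd, rev = pp.core_fwd, pp.core_rev
    if not fwd or not rev:
        raise PanelError("empty primer core")
    report = {
        "fwd_has_no_c": "C" not in fwd,
        "rev_has_no_g": "G" not in rev,
        "cores_have_no_cpg": "CG" not in fwd and "CG" not in rev,
    }
    if template is not None:
        converted = bisulfite_convert(template.upper(), (), "top")
        fwd_conv = _hamming_search(fwd, converted, max_mismatch)
        rev_conv = _hamming_search(rev, reverse_complement(converted), max_mismatch)
        fwd_raw = _hamming_search(fwd, template.upper(), max_mismatch)
        rev_raw = _hamming_search(rev, reverse_complement(template.upper()), max_mismatch)
        report.update(
            fwd_matches_converted=fwd_conv,
            rev_matches_converted=rev_conv,
            no_amplification_unconverted=not (fwd_raw and rev_raw),
        )
    return PrimerValidation(**report)


@dataclass
class AmpliconPanel:
    """An ordered set of targeted amplicons plus the group-truth metadata.

    ``group_methylation`` maps ``amplicon_id -> {group: (mean_pct, sd_pct)}``
    and records the study's per-group amplicon methylation; the simulator
    uses it as ground truth.
    """

    amplicons: list[Amplicon]
    spacer_length: int = 100
    group_methylation: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        ids = [a.amplicon_id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate amplicon ids in panel")

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def get(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.amplicon_id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    @property
    def total_length(self) -> int:
        return sum(a.length for a in self.amplicons)

    @property
    def total_cpg_count(self) -> int:
        return sum(a.declared_cpg_count for a in self.amplicons)

    def cpg_sites(self) -> list[CpGSite]:
        sites: list[CpGSite] = []
        seen: set[tuple[str, int]] = set()
        for a in self.amplicons:
            for s in a.cpg_sites():
                key = (s.gene, s.position)
                if key in seen:
                    raise PanelError(f"duplicate CpG {key} in panel")
                seen.add(key)
                sites.append(s)
        return sites

    def build_reference(self) -> tuple[str, dict[str, int]]:
        """Concatenated fully-converted amplicons separated by N spacers.

        Returns the reference string and a map of each amplicon's 0-based
        offset into it.  Total length is the sum of amplicon lengths plus
        ``spacer_length * (n - 1)``.
        """
        parts: list[str] = []
        offsets: dict[str, int] = {}
        cursor = 0
        for k, a in enumerate(self.amplicons):
            if a.sequence is None:
                raise PanelError(f"amplicon {a.amplicon_id} has no sequence")
            if k:
                parts.append("N" * self.spacer_length)
                cursor += self.spacer_length
            offsets[a.amplicon_id] = cursor
            parts.append(a.converted_sequence())
            cursor += a.length
        return "".join(parts), offsets

    def reference_fasta(self, name: str = "bsas_reference") -> str:
        ref, _ = self.build_reference()
        lines = [f">{name}"] + [ref[i : i + 70] for i in range(0, len(ref), 70)]
        return "\n".join(lines) + "\n"

    def amplicon_bed(self) -> str:
        """BED-like TSV of amplicon offsets in the converted reference."""
        _, offsets = self.build_reference()
        rows = ["chrom\tstart\tend\tamplicon_id\tgene"]
        for a in self.amplicons:
            off = offsets[a.amplicon_id]
            rows.append(f"bsas_reference\t{off}\t{off + a.length}\t{a.amplicon_id}\t{a.gene}")
        return "\n".join(rows) + "\n"

    def with_sequences(self, seed: int = 0) -> "AmpliconPanel":
        """Panel with synthesized sequences for amplicons lacking one."""
        from .simulate import synthesize_amplicon_sequence  # cycle-free at call time

        import numpy as np

        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xA5]))
        out: list[Amplicon] = []
        used: dict[str, set[int]] = {}
        for a in self.amplicons:
            if a.sequence is None:
                a = synthesize_amplicon_sequence(
                    a, rng, forbidden_positions=used.setdefault(a.gene, set())
                )
            used.setdefault(a.gene, set()).update(s.position for s in a.cpg_sites())
            out.append(a)
        return replace(self, amplicons=out)

    # ---- serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "AmpliconPanel":
        amplicons = []
        for row in doc["amplicons"]:
            pr = row["primers"]
            primers = PrimerPair(
                name_fwd=pr["name_fwd"],
                name_rev=pr["name_rev"],
                seq_fwd=pr.get("overhang_fwd", FORWARD_OVERHANG) + pr["core_fwd"]
                if pr.get("with_overhang", True)
                else pr["core_fwd"],
                seq_rev=pr.get("overhang_rev", REVERSE_OVERHANG) + pr["core_rev"]
                if pr.get("with_overhang", True)
                else pr["core_rev"],
                overhang_fwd=pr.get("overhang_fwd", FORWARD_OVERHANG),
                overhang_rev=pr.get("overhang_rev", REVERSE_OVERHANG),
            )
            amplicons.append(
                Amplicon(
                    gene=row["gene"],
                    amplicon_id=row["amplicon_id"],
                    start=row["start"],
                    end=row["end"],
                    primers=primers,
                    declared_length=row.get("length"),
                    declared_cpg_count=row.get("cpg_count", 0),
                    sequence=row.get("sequence"),
                )
            )
        truth = {
            amp_id: {g: (float(m), float(s)) for g, (m, s) in groups.items()}
            for amp_id, groups in doc.get("group_methylation", {}).items()
        }
        return cls(
            amplicons=amplicons,
            spacer_length=doc.get("spacer_length", 100),
            group_methylation=truth,
        )

    @classmethod
    def from_yaml(cls, path) -> "AmpliconPanel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_default_panel() -> AmpliconPanel:
    """The bundled 7-gene / 11-amplicon sex-gene panel (146 CpG sites)."""
    text = resources.files("bsaskit").joinpath("data/default_panel.yaml").read_text()
    doc = yaml.safe_load(text)
    # YAML stores (mean, sd) lists; normalise to tuples via from_dict
    for amp_id, groups in doc.get("group_methylation", {}).items():
        doc["group_methylation"][amp_id] = {g: tuple(v) for g, v in groups.items()}
    return AmpliconPanel.from_dict(doc)
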