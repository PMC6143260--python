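"""Per-CpG methylation calling from bisulfite amplicon reads.

Stages: 3'-end quality trimming at the 95%-call-accuracy threshold, a
minimum-length filter, primer-anchored amplicon assignment, ungapped
bisulfite-aware alignment (a read T opposite an unconverted reference C
is a legal conversion, not a mismatch), per-CpG methylation percentages
as the fraction of unconverted cytosines, and conversion-efficiency QC
over non-CpG cytosines.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .panel import Amplicon, AmpliconPanel, index_to_pos, reverse_complement

_C, _T = ord("C"), ord("T")


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int]
    mate: str = "R1"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


def phred_threshold(min_accuracy: float) -> float:
    """Phred score below which a base call misses the accuracy requirement."""
    if not 0.0 < min_accuracy < 1.0:
        raise ValueError("min_accuracy must be in (0, 1)")
    return -10.0 * math.log10(1.0 - min_accuracy)


def quality_trim(read: ReadRecord, min_accuracy: float = 0.95) -> ReadRecord:
    """Trim low-accuracy bases from the 3' end only.

    Bases are removed from the end while their call accuracy is below
    ``min_accuracy`` (Phred < 13.01 for the default 95%); trimming stops
    at the first passing base, so interior bases are never touched.
    """
    thr = phred_threshold(min_accuracy)
    keep = len(read.qualities)
    while keep > 0 and read.qualities[keep - 1] < thr:
        keep -= 1
    if keep == len(read.qualities):
        return read
    return ReadRecord(read.id, read.sequence[:keep], read.qualities[:keep], read.mate)


def length_filter(
    reads: list[ReadRecord], min_len: int = 100
) -> tuple[list[ReadRecord], int]:
    """Keep reads of length >= min_len; returns (kept, n_removed)."""
    kept = [r for r in reads if len(r) >= min_len]
    return kept, len(reads) - len(kept)


class _AmpliconIndex:
    """Precomputed per-amplicon arrays for fast assignment and alignment."""

    def __init__(self, amplicon: Amplicon):
        if amplicon.sequence is None:
            raise ValueError(f"{amplicon.amplicon_id}: alignment needs a sequence")
        self.amplicon = amplicon
        self.ref = np.frombuffer(amplicon.sequence.encode(), dtype=np.uint8)
        self.conv = np.frombuffer(
            amplicon.converted_sequence().encode(), dtype=np.uint8
        )
        self.is_c = self.ref == _C
        self.cyt_idx = np.nonzero(self.is_c)[0]
        cpg = np.zeros(len(self.ref), dtype=bool)
        cpg[amplicon.cpg_indices()] = True
        self.is_cpg = cpg
        self.fwd_core = np.frombuffer(
            amplicon.primers.core_fwd.encode(), dtype=np.uint8
        )
        self.rev_core = np.frombuffer(
            amplicon.primers.core_rev.encode(), dtype=np.uint8
        )


def build_index(panel: AmpliconPanel) -> dict[str, _AmpliconIndex]:
    return {a.amplicon_id: _AmpliconIndex(a) for a in panel}


def assign_to_amplicon(
    read: ReadRecord,
    panel: AmpliconPanel,
    max_mismatch: int = 2,
    index: dict[str, _AmpliconIndex] | None = None,
) -> tuple[str | None, str | None]:
    """Assign a read to an amplicon by its 5'-end primer sequence.

    The read prefix is compared against every amplicon's converted forward
    primer core (top-strand reads) and reverse primer core (bottom-strand
    mates), allowing ``max_mismatch`` substitutions.  A unique best match
    wins; ties and no-matches are unassigned.  Returns
    ``(amplicon_id, orientation)`` with orientation "fwd" or "rev".
    """
    index = index or build_index(panel)
    r = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
    best: list[tuple[int, str, str]] = []
    for amp_id, ix in index.items():
        for orient, core in (("fwd", ix.fwd_core), ("rev", ix.rev_core)):
            n = len(core)
            if len(r) < n:
                continue
            mism = int(np.count_nonzero(r[:n] != core))
            if mism <= max_mismatch:
                best.append((mism, amp_id, orient))
    if not best:
        return None, None
    best.sort()
    top = [b for b in best if b[0] == best[0][0]]
    if len({b[1] for b in top}) > 1:
        return None, None  # tie across amplicons
    return best[0][1], best[0][2]


@dataclass
class AmpliconAlignment:
    """Ungapped, primer-anchored bisulfite alignment of one read."""

    read_id: str
    amplicon_id: str
    strand: str  # converted-top | converted-bottom
    offset: int
    cyt_indices: np.ndarray  # reference indices of covered cytosines
    cyt_calls: np.ndarray    # uint8 base read at each covered cytosine
    mismatch_count: int


def bisulfite_align(
    read: ReadRecord,
    amplicon: Amplicon | _AmpliconIndex,
    orientation: str = "fwd",
    max_mismatch_frac: float = 0.05,
) -> AmpliconAlignment | None:
    """Align an assigned read to its amplicon with bisulfite-aware scoring.

    Forward reads are anchored at the amplicon 5' end; reverse mates are
    reverse-complemented into top-strand space and anchored at the 3' end.
    A read C or T opposite a reference C are both legal; any other
    disagreement with the converted reference is a mismatch.  Alignments
    with more than ``ceil(max_mismatch_frac * aligned_length)`` mismatches
    are rejected (returns None).
    """
    ix = amplicon if isinstance(amplicon, _AmpliconIndex) else _AmpliconIndex(amplicon)
    L = len(ix.ref)
    if orientation == "fwd":
        seq = read.sequence[:L]
        offset = 0
        strand = "converted-top"
    elif orientation == "rev":
        seq = reverse_complement(read.sequence)
        if len(seq) > L:
            seq = seq[-L:]
        offset = L - len(seq)
        strand = "converted-bottom"
    else:
        raise ValueError(f"orientation must be 'fwd' or 'rev', got {orientation!r}")
    if not seq:
        return None
    r = np.frombuffer(seq.encode(), dtype=np.uint8)
    window = slice(offset, offset + len(r))
    conv = ix.conv[window]
    ref_c = ix.is_c[window]
    mism = int(np.count_nonzero((r != conv) & ~(ref_c & (r == _C))))
    if mism > math.ceil(max_mismatch_frac * len(r)):
        return None
    local = np.nonzero(ref_c)[0]
    return AmpliconAlignment(
        read_id=read.id,
        amplicon_id=ix.amplicon.amplicon_id,
        strand=strand,
        offset=offset,
        cyt_indices=local + offset,
        cyt_calls=r[local],
        mismatch_count=mism,
    )


@dataclass
class MethylationMatrix:
    """Samples x CpG-sites methylation percentages with coverage counts.

    ``long`` has one row per sample x CpG with count_C / count_T /
    count_other and pct_meth = 100*C/(C+T) (missing below min_coverage);
    ``conversion`` holds the per-sample conversion efficiency over
    non-CpG cytosines.
    """

    long: pd.DataFrame
    conversion: pd.DataFrame
    min_coverage: int = 100
    qc: pd.DataFrame | None = None

    def wide(self, value: str = "pct_meth") -> pd.DataFrame:
        return self.long.pivot_table(
            index="sample",
            columns=["gene", "amplicon_id", "position"],
            values=value,
            aggfunc="first",
        )

    def to_tsv(self, path) -> None:
        self.long.to_csv(path, sep="\t", index=False)


def _tally(
    alignments_by_sample: dict[str, list[AmpliconAlignment]],
    index: dict[str, _AmpliconIndex],
):
    """Per-sample, per-amplicon C/T/other counts at every reference cytosine."""
    counts: dict[str, dict[str, np.ndarray]] = {}
    for sample, alns in alignments_by_sample.items():
        per_amp: dict[str, np.ndarray] = {}
        for aln in alns:
            arr = per_amp.get(aln.amplicon_id)
            if arr is None:
                L = len(index[aln.amplicon_id].ref)
                arr = per_amp.setdefault(aln.amplicon_id, np.zeros((3, L), dtype=np.int64))
            calls = aln.cyt_calls
            idx = aln.cyt_indices
            np.add.at(arr[0], idx[calls == _C], 1)
            np.add.at(arr[1], idx[calls == _T], 1)
            np.add.at(arr[2], idx[(calls != _C) & (calls != _T)], 1)
        counts[sample] = per_amp
    return counts


def call_methylation(
    alignments_by_sample: dict[str, list[AmpliconAlignment]],
    panel: AmpliconPanel,
    min_coverage: int = 100,
    index: dict[str, _AmpliconIndex] | None = None,
) -> MethylationMatrix:
    """Per-CpG methylation as the percentage of unconverted cytosine.

    pct_meth = 100 * C / (C + T); sequencing-error ("other") calls are
    excluded from both counts; sites with C + T below ``min_coverage`` get
    a missing percentage but keep their counts.
    """
    index = index or build_index(panel)
    counts = _tally(alignments_by_sample, index)
    rows = []
    conv_rows = []
    for sample in alignments_by_sample:
        per_amp = counts[sample]
        non_cpg_c = non_cpg_t = 0
        for a in panel:
            ix = index[a.amplicon_id]
            arr = per_amp.get(a.amplicon_id)
            if arr is not None:
                mask_non = ix.is_c & ~ix.is_cpg
                non_cpg_c += int(arr[0][mask_non].sum())
                non_cpg_t += int(arr[1][mask_non].sum())
            for i in a.cpg_indices():
                c = int(arr[0][i]) if arr is not None else 0
                t = int(arr[1][i]) if arr is not None else 0
                o = int(arr[2][i]) if arr is not None else 0
                cov = c + t
                pct = 100.0 * c / cov if cov >= min_coverage and cov > 0 else np.nan
                rows.append(
                    (sample, a.gene, a.amplicon_id, index_to_pos(a.start, i), c, t, o, pct)
                )
        denom = non_cpg_c + non_cpg_t
        eff = 100.0 * non_cpg_t / denom if denom else np.nan
        conv_rows.append((sample, eff, non_cpg_c, non_cpg_t))
    long = pd.DataFrame(
        rows,
        columns=[
            "sample", "gene", "amplicon_id", "position",
            "count_C", "count_T", "count_other", "pct_meth",
        ],
    )
    conv = pd.DataFrame(
        conv_rows, columns=["sample", "efficiency_pct", "non_cpg_C", "non_cpg_T"]
    )
    return MethylationMatrix(long=long, conversion=conv, min_coverage=min_coverage)


def conversion_efficiency(
    alignments_by_sample: dict[str, list[AmpliconAlignment]],
    panel: AmpliconPanel,
    warn_below: float = 98.0,
    index: dict[str, _AmpliconIndex] | None = None,
) -> pd.DataFrame:
    """Bisulfite conversion efficiency per sample.

    100 * T / (C + T) over all non-CpG reference cytosines; a retained C
    outside a CpG context indicates incomplete conversion.  Samples below
    ``warn_below`` percent, or with no covered non-CpG cytosine, trigger a
    warning.
    """
    index = index or build_index(panel)
    matrix = call_methylation(alignments_by_sample, panel, min_coverage=1, index=index)
    conv = matrix.conversion
    for _, row in conv.iterrows():
        if np.isnan(row.efficiency_pct):
            warnings.warn(
                f"{row['sample']}: no non-CpG cytosines covered; "
                "conversion efficiency undefined"
            )
        elif row.efficiency_pct < warn_below:
            warnings.warn(
                f"{row['sample']}: conversion efficiency "
                f"{row.efficiency_pct:.2f}% below {warn_below}%"
            )
    return conv


def quantify_samples(
    sample_reads: dict[str, list[ReadRecord]],
    panel: AmpliconPanel,
    min_accuracy: float = 0.95,
    min_len: int = 100,
    max_primer_mismatch: int = 2,
    max_mismatch_frac: float = 0.05,
    min_coverage: int = 100,
) -> MethylationMatrix:
    """Full quantification: trim, filter, assign, align, call.

    Read accounting is conserved: filtered + unassigned + rejected +
    aligned equals the input count per sample (see the ``qc`` table on
    the returned matrix).
    """
    index = build_index(panel)
    alignments: dict[str, list[AmpliconAlignment]] = {}
    qc_rows = []
    for sample, reads in sample_reads.items():
        trimmed = [quality_trim(r, min_accuracy) for r in reads]
        kept, n_short = length_filter(trimmed, min_len)
        n_unassigned = n_rejected = 0
        alns: list[AmpliconAlignment] = []
        for read in kept:
            amp_id, orient = assign_to_amplicon(
                read, panel, max_primer_mismatch, index=index
            )
            if amp_id is None:
                n_unassigned += 1
                continue
            aln = bisulfite_align(read, index[amp_id], orient, max_mismatch_frac)
            if aln is None:
                n_rejected += 1
            else:
                alns.append(aln)
        alignments[sample] = alns
        qc_rows.append(
            (sample, len(reads), n_short, n_unassigned, n_rejected, len(alns))
        )
    matrix = call_methylation(alignments, panel, min_coverage, index=index)
    matrix.qc = pd.DataFrame(
        qc_rows,
        columns=["sample", "reads_in", "too_short", "unassigned", "align_rejected", "aligned"],
    )
    return matrix


def read_fastq(path) -> list[ReadRecord]:
    """Read a FASTQ (optionally gzipped) into ReadRecords."""
    path = Path(path)
    mate = "R2" if "_R2" in path.name or ".R2." in path.name else "R1"
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [
            ReadRecord(
                rec.id, str(rec.seq), rec.letter_annotations["phred_quality"], mate
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def quantify_fastq_dir(
    fastq_dir, panel: AmpliconPanel, **kwargs
) -> MethylationMatrix:
    """Quantify every sample in a directory of ``<sample>_R1/_R2`` FASTQs."""
    fastq_dir = Path(fastq_dir)
    sample_reads: dict[str, list[ReadRecord]] = {}
    for path in sorted(fastq_dir.glob("*_R[12].fastq*")):
        sample = path.name.split("_R1")[0].split("_R2")[0]
        sample_reads.setdefault(sample, []).extend(read_fastq(path))
    if not sample_reads:
        raise FileNotFoundError(f"no *_R1/_R2 FASTQ files under {fastq_dir}")
    return quantify_samples(sample_reads, panel, **kwargs)
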