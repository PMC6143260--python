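"""Seeded synthetic data: bisulfite amplicon reads, qPCR Ct tables, toy isoforms.

The generator reproduces the statistical structure the downstream analysis
assumes: a four-group gonad cohort (captive/wild x testes/ovaries, default
14/10/14/4), per-sample amplicon methylation drawn from Beta distributions
moment-matched to each group's mean +/- SD, per-CpG Gaussian jitter,
directional bisulfite PCR with incomplete conversion at a configurable
failure rate, substitution sequencing errors with matching Phred scores,
triplicate qPCR Ct values with a configurable true fold change, and toy
dmrt1-like / cyp19a1-like gene models with sex-specific splice variants.
Every output is deterministic given the seed, and ground-truth tables are
emitted for parameter-recovery tests.
"""

from __future__ import annotations

import gzip
import math
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Amplicon, AmpliconPanel, index_to_pos, reverse_complement
from .quantify import ReadRecord
from .splice import GeneModel, Isoform, SpliceEvent
from . import panel as _panel_mod

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b
# substitution table: for base b and draw k in {0,1,2}, the k-th other base
_SUB = np.zeros((256, 3), dtype=np.uint8)
for b in b"ACGTN":
    others = [x for x in b"ACGT" if x != b][:3]
    _SUB[b] = others


def _rng_from(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *stream]))


@dataclass(frozen=True)
class GroupSpec:
    sex: str      # testes | ovaries
    origin: str   # captive | wild
    n: int

    @property
    def label(self) -> str:
        return f"{self.origin}_{self.sex}"


@dataclass
class CohortDesign:
    """Sex x origin group sizes of the cohort."""

    groups: list[GroupSpec]

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.n < 1:
                raise ValueError(f"group {g.label} needs n >= 1")

    @property
    def n_samples(self) -> int:
        return sum(g.n for g in self.groups)

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for i in range(1, g.n + 1):
                rows.append((f"{g.label}_{i:02d}", g.label, g.sex, g.origin))
        return pd.DataFrame(rows, columns=["sample", "group", "sex", "origin"])


def default_design() -> CohortDesign:
    """The study cohort: 42 gonads = 24 testes + 18 ovaries."""
    return CohortDesign(
        [
            GroupSpec("testes", "captive", 14),
            GroupSpec("testes", "wild", 10),
            GroupSpec("ovaries", "captive", 14),
            GroupSpec("ovaries", "wild", 4),
        ]
    )


@dataclass
class MethylationTruth:
    """Per (group, amplicon) mean/SD methylation percentages."""

    group_amplicon: dict[str, dict[str, tuple[float, float]]]

    @classmethod
    def from_panel(cls, panel: AmpliconPanel) -> "MethylationTruth":
        if not panel.group_methylation:
            raise ValueError("panel carries no group methylation truth")
        return cls({k: dict(v) for k, v in panel.group_methylation.items()})

    def get(self, group: str, amplicon_id: str) -> tuple[float, float]:
        return self.group_amplicon[amplicon_id][group]


@dataclass
class SimulationConfig:
    design: CohortDesign = field(default_factory=default_design)
    coverage_per_amplicon: int = 2000
    conversion_failure_rate: float = 0.005
    sequencing_error_rate: float = 0.001
    read_length: int = 300
    paired: bool = True
    cpg_jitter_sd: float = 2.0  # percentage points
    three_prime_decay: int = 0  # bases ramping down to Q2 at the 3' end
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_failure_rate", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coverage_per_amplicon < 1:
            raise ValueError("coverage must be >= 1")


# ---------------------------------------------------------------------------
# amplicon sequence synthesis

_FILL_BASES = np.frombuffer(b"ATGC", dtype=np.uint8)
_FILL_P = np.array([0.30, 0.30, 0.20, 0.20])


def synthesize_amplicon_sequence(
    amplicon: Amplicon,
    rng: np.random.Generator,
    forbidden_positions: set[int] | None = None,
) -> Amplicon:
    """Attach a synthetic unconverted top-strand sequence to an amplicon.

    The sequence starts with the forward primer core (which contains no C,
    so it equals its own bisulfite conversion) and ends with the reverse
    complement of the reverse core; exactly ``declared_cpg_count`` CG
    dinucleotides are placed in the interior, spaced at least 3 bp apart,
    avoiding ``forbidden_positions`` (TSS-relative CpG positions already
    used by other amplicons of the same gene).  Interior fill contains
    non-CpG cytosines for conversion-efficiency QC but never creates an
    extra CG.
    """
    forbidden = forbidden_positions or set()
    fwd = amplicon.primers.core_fwd
    tail = reverse_complement(amplicon.primers.core_rev)
    L = amplicon.length
    m = L - len(fwd) - len(tail)
    k = amplicon.declared_cpg_count
    if m < 3 * k + 2:
        raise ValueError(
            f"{amplicon.amplicon_id}: interior of {m} bp cannot hold {k} CpGs"
        )
    # evenly spaced CpG starts within the interior, nudged off forbidden positions
    starts = []
    for j in range(k):
        p = int(round((j + 0.5) * (m - 2) / k))
        p = min(max(p, 1), m - 3)
        while (
            p in (q for q in starts)
            or any(abs(p - q) < 3 for q in starts)
            or index_to_pos(amplicon.start, len(fwd) + p) in forbidden
        ):
            p += 1
            if p > m - 3:
                raise ValueError(f"{amplicon.amplicon_id}: CpG placement failed")
        starts.append(p)
    starts.sort()
    interior = np.zeros(m, dtype=np.uint8)
    placed = set()
    for p in starts:
        interior[p], interior[p + 1] = ord("C"), ord("G")
        placed.update((p, p + 1))
    prev = ord(fwd[-1])
    draws = rng.choice(_FILL_BASES, size=2 * m, p=_FILL_P)
    d = 0
    for i in range(m):
        if i in placed:
            prev = interior[i]
            continue
        b = draws[d]; d += 1
        while (prev == ord("C") and b == ord("G")) or (i == m - 1 and b == ord("C")):
            b = draws[d % len(draws)]; d += 1
        interior[i] = b
        prev = b
    seq = fwd + interior.tobytes().decode() + tail
    return replace(amplicon, sequence=seq)


# ---------------------------------------------------------------------------
# methylation truth sampling

def beta_params(mean_pct: float, sd_pct: float) -> tuple[float, float] | None:
    """Moment-matched Beta(a, b) for a mean/SD in percent, or None when the
    variance bound mean*(1-mean) makes matching infeasible."""
    m, s = mean_pct / 100.0, sd_pct / 100.0
    if s <= 0 or m <= 0 or m >= 1:
        return None
    v = s * s
    bound = m * (1 - m)
    if v >= bound:
        return None
    k = bound / v - 1.0
    return m * k, (1.0 - m) * k


def sample_methylation_profiles(
    truth: MethylationTruth,
    design: CohortDesign,
    panel: AmpliconPanel,
    seed: int = 0,
    cpg_jitter_sd: float = 2.0,
) -> pd.DataFrame:
    """Per-sample, per-CpG true methylation fractions.

    Each sample draws one amplicon-level value from the moment-matched
    Beta (point mass when SD is zero or infeasible, with a warning in the
    infeasible case), clipped to [0.001, 0.999]; per-CpG values add
    mean-zero Gaussian jitter of ``cpg_jitter_sd`` percentage points,
    clipped to [0, 1].  The expected group mean equals the configured mean.
    """
    rng = _rng_from(seed, 1)
    samples = design.sample_table()
    rows = []
    for amp in panel:
        sites = amp.cpg_sites()
        for _, srow in samples.iterrows():
            mean_pct, sd_pct = truth.get(srow.group, amp.amplicon_id)
            params = beta_params(mean_pct, sd_pct)
            if params is None:
                if sd_pct > 0:
                    warnings.warn(
                        f"{amp.amplicon_id}/{srow.group}: SD {sd_pct} infeasible for "
                        f"mean {mean_pct}; using point mass"
                    )
                level = mean_pct / 100.0
            else:
                level = rng.beta(*params)
            level = min(max(level, 0.001), 0.999)
            jitter = rng.normal(0.0, cpg_jitter_sd / 100.0, size=len(sites))
            vals = np.clip(level + jitter, 0.0, 1.0)
            for site, v in zip(sites, vals):
                rows.append(
                    (srow["sample"], srow.group, amp.gene, amp.amplicon_id,
                     site.position, float(v))
                )
    return pd.DataFrame(
        rows, columns=["sample", "group", "gene", "amplicon_id", "position", "true_meth"]
    )


# ---------------------------------------------------------------------------
# read simulation

def _apply_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return mat
    hit = rng.random(mat.shape) < rate
    if hit.any():
        mat = mat.copy()
        which = rng.integers(0, 3, size=int(hit.sum()))
        mat[hit] = _SUB[mat[hit], which]
    return mat


def _qualities(n: int, error_rate: float, decay: int) -> list[int]:
    q = 40 if error_rate <= 0 else min(40, round(-10 * math.log10(error_rate)))
    quals = [q] * n
    if decay > 0:
        ramp = min(decay, n)
        for j in range(ramp):
            # linear ramp down to Q2 at the very 3' end
            quals[n - ramp + j] = max(2, round(q - (q - 2) * (j + 1) / ramp))
    return quals


def simulate_amplicon_reads(
    sample_id: str,
    amplicon: Amplicon,
    true_meth: np.ndarray,
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Paired directional bisulfite reads for one sample x amplicon.

    Per template molecule each cytosine is retained as C if it is a
    methylated CpG (probability ``true_meth`` at its site) or by
    incomplete conversion (probability ``conversion_failure_rate`` for any
    unmethylated C); otherwise it reads T.  R1 is the converted top strand
    from the forward primer, R2 its reverse complement from the reverse
    primer, truncated to ``read_length``, with independent substitution
    errors and Phred scores consistent with the error rate.  Read names
    encode sample and amplicon for truth-tracking only.
    """
    if amplicon.sequence is None:
        raise ValueError(f"{amplicon.amplicon_id}: simulate needs a sequence")
    L = amplicon.length
    if L > 2 * config.read_length:
        raise ValueError(
            f"{amplicon.amplicon_id}: {L} bp not representable as a "
            f"2 x {config.read_length} bp overlapping pair"
        )
    cpg_idx = np.array(amplicon.cpg_indices(), dtype=np.int64)
    if len(true_meth) != len(cpg_idx):
        raise ValueError("true_meth length must match the amplicon CpG count")
    ref = np.frombuffer(amplicon.sequence.encode(), dtype=np.uint8)
    c_idx = np.nonzero(ref == ord("C"))[0]
    non_cpg_c = np.setdiff1d(c_idx, cpg_idx)

    rng = _rng_from(
        seed, 2,
        zlib.crc32(sample_id.encode()) & 0x7FFFFFFF,
        zlib.crc32(amplicon.amplicon_id.encode()) & 0x7FFFFFFF,
    )
    n = config.coverage_per_amplicon
    conv = np.frombuffer(
        amplicon.converted_sequence().encode(), dtype=np.uint8
    )
    mat = np.tile(conv, (n, 1))
    if len(cpg_idx):
        methylated = rng.random((n, len(cpg_idx))) < true_meth[None, :]
        fail_cpg = rng.random((n, len(cpg_idx))) < config.conversion_failure_rate
        keep_c = methylated | fail_cpg
        cols = np.broadcast_to(cpg_idx, keep_c.shape)
        mat[np.nonzero(keep_c)[0], cols[keep_c]] = ord("C")
    if len(non_cpg_c) and config.conversion_failure_rate > 0:
        fail = rng.random((n, len(non_cpg_c))) < config.conversion_failure_rate
        cols = np.broadcast_to(non_cpg_c, fail.shape)
        mat[np.nonzero(fail)[0], cols[fail]] = ord("C")

    r1 = mat[:, : config.read_length]
    r2 = _COMP[mat][:, ::-1][:, : config.read_length]
    r1 = _apply_errors(r1, config.sequencing_error_rate, rng)
    r2 = _apply_errors(r2, config.sequencing_error_rate, rng)
    q1 = _qualities(r1.shape[1], config.sequencing_error_rate, config.three_prime_decay)
    q2 = _qualities(r2.shape[1], config.sequencing_error_rate, config.three_prime_decay)
    amp_tag = amplicon.amplicon_id.replace(" ", "")
    reads1, reads2 = [], []
    for i in range(n):
        name = f"{sample_id}|{amp_tag}|{i}"
        reads1.append(ReadRecord(f"{name}/1", r1[i].tobytes().decode(), list(q1), "R1"))
        reads2.append(ReadRecord(f"{name}/2", r2[i].tobytes().decode(), list(q2), "R2"))
    return reads1, reads2


@dataclass
class SimulatedCohort:
    panel: AmpliconPanel          # materialized panel (with sequences)
    design: CohortDesign
    truth: pd.DataFrame           # sample, group, gene, amplicon_id, position, true_meth
    reads: dict[str, tuple[list[ReadRecord], list[ReadRecord]]]

    @property
    def n_reads(self) -> int:
        return sum(len(r1) + len(r2) for r1, r2 in self.reads.values())

    def sample_reads(self) -> dict[str, list[ReadRecord]]:
        """R1+R2 merged per sample, as the quantifier consumes them."""
        return {s: list(r1) + list(r2) for s, (r1, r2) in self.reads.items()}

    def write_fastq(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, (r1, r2) in self.reads.items():
            for mate, reads in (("R1", r1), ("R2", r2)):
                with gzip.open(outdir / f"{sample}_{mate}.fastq.gz", "wt") as fh:
                    for r in reads:
                        quals = "".join(chr(q + 33) for q in r.qualities)
                        fh.write(f"@{r.id}\n{r.sequence}\n+\n{quals}\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.design.sample_table().to_csv(outdir / "design.tsv", sep="\t", index=False)


def simulate_cohort(
    config: SimulationConfig,
    panel: AmpliconPanel | None = None,
    truth: MethylationTruth | None = None,
    outdir=None,
) -> SimulatedCohort:
    """One R1/R2 read set per sample spanning all panel amplicons.

    Deterministic given ``config.seed``; total reads equal
    n_samples x n_amplicons x coverage x 2 mates.
    """
    panel = panel or _panel_mod.load_default_panel()
    if any(a.sequence is None for a in panel):
        panel = panel.with_sequences(config.seed)
    truth = truth or MethylationTruth.from_panel(panel)
    profiles = sample_methylation_profiles(
        truth, config.design, panel, seed=config.seed, cpg_jitter_sd=config.cpg_jitter_sd
    )
    reads: dict[str, tuple[list[ReadRecord], list[ReadRecord]]] = {}
    by_sample_amp = profiles.set_index(["sample", "amplicon_id"]).sort_index()
    for sample in config.design.sample_table()["sample"]:
        all_r1: list[ReadRecord] = []
        all_r2: list[ReadRecord] = []
        for amp in panel:
            sub = by_sample_amp.loc[[(sample, amp.amplicon_id)]]
            # truth rows are emitted in sequence order (ascending position)
            tm = sub.sort_values("position")["true_meth"].to_numpy()
            r1, r2 = simulate_amplicon_reads(sample, amp, tm, config, config.seed)
            all_r1.extend(r1)
            all_r2.extend(r2)
        reads[sample] = (all_r1, all_r2)
    cohort = SimulatedCohort(panel=panel, design=config.design, truth=profiles, reads=reads)
    if outdir is not None:
        cohort.write_fastq(outdir)
    return cohort


# ---------------------------------------------------------------------------
# qPCR simulation

@dataclass
class QpcrTruth:
    """Ground truth for the qPCR simulator (one target gene vs a reference)."""

    target_gene: str = "dmrt1"
    reference_gene: str = "ubq"
    fold_change: float = 1.9      # testes : ovaries ratio of mean 2^-dCt
    base_ct_target: float = 24.0  # Ct of the target at ovary expression level
    base_ct_reference: float = 18.0
    ct_noise_sd: float = 0.2
    replicates: int = 3
    sample_log2_sd: float = 0.0   # optional between-individual spread

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be > 0")


def simulate_qpcr(
    qtruth: QpcrTruth,
    design: dict[str, int] | CohortDesign | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate Ct values for target and reference genes per sample.

    Ct(target) = base_ct - log2(expression) + noise; the expression of
    every ovary sample is 1 and of every testis sample ``fold_change``, so
    the testes:ovaries ratio of mean 2^-dCt equals the configured fold
    change in expectation (the lognormal noise bias is identical in both
    groups and cancels).
    """
    if design is None:
        design = {"testes": 10, "ovaries": 10}
    if isinstance(design, CohortDesign):
        counts: dict[str, int] = {}
        for g in design.groups:
            counts[g.sex] = counts.get(g.sex, 0) + g.n
        design = counts
    rng = _rng_from(seed, 3)
    rows = []
    for sex, n in design.items():
        base_expr = qtruth.fold_change if sex == "testes" else 1.0
        for i in range(1, n + 1):
            sample = f"{sex}_{i:02d}"
            log2_expr = math.log2(base_expr)
            if qtruth.sample_log2_sd > 0:
                log2_expr += rng.normal(0.0, qtruth.sample_log2_sd)
            for gene, base_ct, shift in (
                (qtruth.target_gene, qtruth.base_ct_target, log2_expr),
                (qtruth.reference_gene, qtruth.base_ct_reference, 0.0),
            ):
                for rep in range(1, qtruth.replicates + 1):
                    ct = base_ct - shift + rng.normal(0.0, qtruth.ct_noise_sd)
                    rows.append((sample, sex, gene, rep, float(ct)))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])


# ---------------------------------------------------------------------------
# toy gene models / isoforms

@dataclass
class ToyIsoformSet:
    models: dict[str, GeneModel]
    isoforms: dict[str, Isoform]
    transcripts: dict[str, str]
    assay_primers: dict[str, "object"]
    truth_events: dict[str, list[SpliceEvent]]

    def transcript_fasta(self) -> str:
        out = []
        for name, seq in self.transcripts.items():
            out.append(f">{name}")
            out.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
        return "\n".join(out) + "\n"

    def gene_model_tsv(self) -> str:
        rows = ["gene\texon\tstart\tend"]
        for gene, model in self.models.items():
            for name, s, e in model.exons:
                rows.append(f"{gene}\t{name}\t{s}\t{e}")
        return "\n".join(rows) + "\n"


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def simulate_isoforms(seed: int = 0) -> ToyIsoformSet:
    """Toy sex-specific splice variants of a dmrt1-like and cyp19a1-like gene.

    dmrt1 toy: reference exons 1a (250 bp, harbouring a DM-domain interval
    at transcript positions 40-160), 2 and 3; the ovary variant replaces
    exon 1a with an untranslated 59-bp exon 1b located 3,357 bp upstream,
    so females lack the DM domain.  cyp19a1 toy: nine reference exons with
    exon 1 = 196 bp and exon 2 = 151 bp; the testis variants shorten
    exon 1 to 163 bp (3' loss of 33) and exon 2 to 101 bp (5' loss of 50),
    with exon 3 occasionally spliced out.  Assay primer pairs reproduce the
    575-bp testis-specific and 207-bp ovary-specific products.
    """
    from .panel import PrimerPair

    rng = _rng_from(seed, 4)

    # ---- dmrt1-like gene
    d_genomic = _random_dna(rng, 5200)
    d_exons = [("exon1a", 3457, 3706), ("exon2", 4000, 4199), ("exon3", 4500, 4799)]
    dmrt1 = GeneModel(
        gene="dmrt1",
        exons=d_exons,
        genomic_sequence=d_genomic,
        annotated_domains=[("DM", (40, 160))],
    )
    testis_chain = [(s, e) for _, s, e in d_exons]
    ovary_chain = [(100, 158)] + testis_chain[1:]  # exon 1b is 59 bp, 3357 bp upstream
    d_testis = Isoform("dmrt1_testis", testis_chain)
    d_testis.sequence = d_testis.splice_from(d_genomic)
    d_ovary = Isoform("dmrt1_ovary", ovary_chain)
    d_ovary.sequence = d_ovary.splice_from(d_genomic)
    t = d_testis.sequence
    male_primers = PrimerPair(
        name_fwd="DMRT1_Male_F", name_rev="DMRT1_Male_R",
        seq_fwd=t[5:25], seq_rev=reverse_complement(t[560:580]),
        overhang_fwd="", overhang_rev="",
    )  # forward 5' at transcript position 6, reverse footprint ends at 580 -> 575 bp

    # ---- cyp19a1-like gene
    exon_lengths = [196, 151, 120, 140, 130, 150, 120, 110, 160]
    intron = 150
    c_exons: list[tuple[str, int, int]] = []
    pos = 201
    for i, ln in enumerate(exon_lengths, start=1):
        c_exons.append((f"exon{i}", pos, pos + ln - 1))
        pos += ln + intron
    c_genomic = _random_dna(rng, pos + 200)
    cyp19a1 = GeneModel(gene="cyp19a1", exons=c_exons, genomic_sequence=c_genomic)
    full_chain = [(s, e) for _, s, e in c_exons]
    c_ovary = Isoform("cyp19a1_ovary", full_chain)
    c_ovary.sequence = c_ovary.splice_from(c_genomic)
    short_chain = [
        (full_chain[0][0], full_chain[0][1] - 33),   # exon 1: 196 -> 163
        (full_chain[1][0] + 50, full_chain[1][1]),   # exon 2: 151 -> 101
    ] + full_chain[2:]
    c_testis_a = Isoform("cyp19a1_testis_a", short_chain)
    c_testis_a.sequence = c_testis_a.splice_from(c_genomic)
    skip3_chain = short_chain[:2] + short_chain[3:]  # exon 3 spliced out
    c_testis_b = Isoform("cyp19a1_testis_b", skip3_chain)
    c_testis_b.sequence = c_testis_b.splice_from(c_genomic)
    o = c_ovary.sequence
    female_primers = PrimerPair(
        name_fwd="CYP19a_Female_F", name_rev="CYP19a_Female_R1",
        seq_fwd=o[0:20], seq_rev=reverse_complement(o[187:207]),
        overhang_fwd="", overhang_rev="",
    )  # reverse footprint 188-207 spans the full-length exon1/exon2 junction -> 207 bp

    truth_events = {
        "dmrt1_testis": [],
        "dmrt1_ovary": [
            SpliceEvent("novel_exon", "segment@100", 59),
            SpliceEvent("exon_skipped", "exon1a", -250),
        ],
        "cyp19a1_ovary": [],
        "cyp19a1_testis_a": [
            SpliceEvent("exon_shortened_3p", "exon1", -33),
            SpliceEvent("exon_shortened_5p", "exon2", -50),
        ],
        "cyp19a1_testis_b": [
            SpliceEvent("exon_shortened_3p", "exon1", -33),
            SpliceEvent("exon_shortened_5p", "exon2", -50),
            SpliceEvent("exon_skipped", "exon3", -120),
        ],
    }
    isoforms = {
        iso.transcript_id: iso
        for iso in (d_testis, d_ovary, c_ovary, c_testis_a, c_testis_b)
    }
    return ToyIsoformSet(
        models={"dmrt1": dmrt1, "cyp19a1": cyp19a1},
        isoforms=isoforms,
        transcripts={k: v.sequence for k, v in isoforms.items()},
        assay_primers={"dmrt1_male": male_primers, "cyp19a1_female": female_primers},
        truth_events=truth_events,
    )
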