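"""Quantification: trimming, filtering, assignment, alignment, calling."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from bsaskit.panel import reverse_complement
from bsaskit.quantify import (
    ReadRecord,
    assign_to_amplicon,
    bisulfite_align,
    build_index,
    call_methylation,
    conversion_efficiency,
    length_filter,
    quality_trim,
    quantify_samples,
    read_fastq,
)
from bsaskit.simulate import (
    CohortDesign,
    GroupSpec,
    SimulationConfig,
    simulate_amplicon_reads,
    simulate_cohort,
)


def _read(seq, quals=None, mate="R1", rid="r1"):
    return ReadRecord(rid, seq, quals or [40] * len(seq), mate)


class TestQualityTrim:
    def test_trims_low_accuracy_suffix(self):
        read = _read("ACGTACGT", [30, 30, 30, 30, 30, 30, 12, 10])
        trimmed = quality_trim(read)
        assert trimmed.sequence == "ACGTAC"
        assert trimmed.qualities == [30] * 6

    def test_high_quality_identity(self):
        read = _read("ACGT", [14, 14, 14, 14])
        assert quality_trim(read) is read

    def test_stops_at_first_passing_base(self):
        # interior low-quality bases survive once a passing base is hit
        read = _read("ACGTACGT", [10, 30, 10, 30, 10, 30, 10, 30])
        assert quality_trim(read).sequence == "ACGTACGT"

    def test_q13_is_below_95pct_accuracy(self):
        read = _read("ACGT", [30, 30, 30, 13])
        assert quality_trim(read).sequence == "ACG"


class TestLengthFilter:
    def test_boundary_semantics(self):
        r99 = _read("A" * 99)
        r100 = _read("A" * 100)
        kept, removed = length_filter([r99, r100])
        assert kept == [r100] and removed == 1

    def test_conservation(self, rng):
        reads = [_read("A" * int(n)) for n in rng.integers(50, 150, size=40)]
        kept, removed = length_filter(reads)
        assert len(kept) + removed == len(reads)


class TestAssignment:
    def test_exact_forward_core(self, materialized_panel):
        index = build_index(materialized_panel)
        for amp in materialized_panel:
            read = _read(amp.converted_sequence()[:60])
            amp_id, orient = assign_to_amplicon(read, materialized_panel, index=index)
            assert (amp_id, orient) == (amp.amplicon_id, "fwd")

    def test_reverse_mate(self, materialized_panel):
        amp = materialized_panel.get("amh")
        r2 = reverse_complement(amp.converted_sequence())[:60]
        amp_id, orient = assign_to_amplicon(_read(r2, mate="R2"), materialized_panel)
        assert (amp_id, orient) == ("amh", "rev")

    def test_random_read_unassigned(self, materialized_panel, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        assert assign_to_amplicon(_read(seq), materialized_panel) == (None, None)

    def test_tie_between_amplicons_unassigned(self, materialized_panel):
        # two amplicons sharing a forward primer core force a tie
        a = materialized_panel.get("cyp19a1")
        clone = dataclasses.replace(
            a, amplicon_id="cyp19a1-copy", sequence=a.sequence
        )
        panel = dataclasses.replace(
            materialized_panel, amplicons=[a, clone], group_methylation={}
        )
        read = _read(a.converted_sequence()[:60])
        assert assign_to_amplicon(read, panel) == (None, None)


class TestBisulfiteAlign:
    def _reads(self, amp, meth, seed=0, **kw):
        cfg = SimulationConfig(
            coverage_per_amplicon=3, conversion_failure_rate=0.0,
            sequencing_error_rate=0.0, **kw,
        )
        return simulate_amplicon_reads(
            "s", amp, np.full(amp.declared_cpg_count, meth), cfg, seed
        )

    def test_unmethylated_read_all_t_calls(self, materialized_panel):
        amp = materialized_panel.get("cyp19a1")
        r1, _ = self._reads(amp, 0.0)
        aln = bisulfite_align(r1[0], amp, "fwd")
        assert aln.mismatch_count == 0
        assert bytes(aln.cyt_calls).decode() == "T" * len(aln.cyt_indices)

    def test_fully_methylated_read_c_at_cpg_only(self, materialized_panel):
        amp = materialized_panel.get("cyp19a1")
        r1, _ = self._reads(amp, 1.0)
        aln = bisulfite_align(r1[0], amp, "fwd")
        cpg = set(amp.cpg_indices())
        for idx, call in zip(aln.cyt_indices, aln.cyt_calls):
            assert chr(call) == ("C" if idx in cpg else "T")

    def test_reverse_mate_alignment_offset(self, materialized_panel):
        amp = materialized_panel.get("dmrt1 (2)")  # 428 bp, longer than one read
        _, r2 = self._reads(amp, 0.0)
        aln = bisulfite_align(r2[0], amp, "rev")
        assert aln.strand == "converted-bottom"
        assert aln.offset == amp.length - 300

    def test_single_substitution_is_other_call(self, materialized_panel):
        amp = materialized_panel.get("cyp19a1")
        r1, _ = self._reads(amp, 1.0)
        read = r1[0]
        i = amp.cpg_indices()[3]
        seq = read.sequence[:i] + "G" + read.sequence[i + 1 :]
        aln = bisulfite_align(dataclasses.replace(read, sequence=seq), amp, "fwd")
        calls = dict(zip(aln.cyt_indices, aln.cyt_calls))
        assert chr(calls[i]) == "G"  # neither C nor T -> excluded from counts
        assert aln.mismatch_count == 1

    def test_excessive_mismatches_rejected(self, materialized_panel, rng):
        amp = materialized_panel.get("cyp19a1")
        seq = amp.converted_sequence()
        # corrupt 10% of positions away from bisulfite-legal space
        n_bad = len(seq) // 10
        bad = rng.choice(len(seq), size=n_bad, replace=False)
        chars = list(seq)
        for i in bad:
            chars[i] = {"A": "G", "C": "A", "G": "A", "T": "A"}[chars[i]]
        assert bisulfite_align(_read("".join(chars)), amp, "fwd") is None


class TestCalling:
    def test_percentages_from_counts(self, materialized_panel):
        amp = materialized_panel.get("cyp19a1")
        cfg = SimulationConfig(
            coverage_per_amplicon=100, conversion_failure_rate=0.0,
            sequencing_error_rate=0.0,
        )
        half = np.zeros(amp.declared_cpg_count)
        half[0] = 1.0  # first CpG always methylated, rest never
        r1, r2 = simulate_amplicon_reads("s", amp, half, cfg, seed=0)
        alns = [bisulfite_align(r, amp, "fwd") for r in r1] + [
            bisulfite_align(r, amp, "rev") for r in r2
        ]
        matrix = call_methylation({"s": alns}, _single_panel(materialized_panel), 100)
        by_pos = matrix.long.set_index("position")
        sites = amp.cpg_sites()
        assert by_pos.loc[sites[0].position, "pct_meth"] == 100.0
        assert (by_pos.loc[[s.position for s in sites[1:]], "pct_meth"] == 0.0).all()

    def test_min_coverage_flags_missing(self, materialized_panel):
        amp = materialized_panel.get("cyp19a1")
        cfg = SimulationConfig(
            coverage_per_amplicon=10, conversion_failure_rate=0.0,
            sequencing_error_rate=0.0,
        )
        r1, _ = simulate_amplicon_reads(
            "s", amp, np.zeros(amp.declared_cpg_count), cfg, 0
        )
        alns = [bisulfite_align(r, amp, "fwd") for r in r1]
        matrix = call_methylation({"s": alns}, _single_panel(materialized_panel), 100)
        assert matrix.long.pct_meth.isna().all()
        assert (matrix.long.count_T == 10).all()


def _single_panel(panel, amp_id="cyp19a1"):
    return dataclasses.replace(
        panel, amplicons=[panel.get(amp_id)], group_methylation={}
    )


class TestConversionEfficiency:
    def test_matches_simulator_rate(self, materialized_panel):
        amp = materialized_panel.get("cyp19a1")
        cfg = SimulationConfig(
            coverage_per_amplicon=2000, conversion_failure_rate=0.005,
            sequencing_error_rate=0.0,
        )
        r1, _ = simulate_amplicon_reads(
            "s", amp, np.zeros(amp.declared_cpg_count), cfg, 0
        )
        alns = [bisulfite_align(r, amp, "fwd") for r in r1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            conv = conversion_efficiency({"s": alns}, _single_panel(materialized_panel))
        assert conv.efficiency_pct.iloc[0] == pytest.approx(99.5, abs=0.2)

    def test_no_noncpg_cytosines_warns(self, materialized_panel):
        with pytest.warns(UserWarning, match="undefined"):
            conversion_efficiency({"s": []}, _single_panel(materialized_panel))


class TestPipelineProperties:
    def test_read_accounting_conserved(self, small_cohort):
        matrix = quantify_samples(
            small_cohort.sample_reads(), small_cohort.panel, min_coverage=10
        )
        qc = matrix.qc
        assert (
            qc.too_short + qc.unassigned + qc.align_rejected + qc.aligned == qc.reads_in
        ).all()

    def test_caller_equals_truth_tally_oracle(self, materialized_panel):
        """On error-free reads the pipeline must equal a direct per-position
        tally keyed by the simulator's truth-tracking read names."""
        design = CohortDesign([GroupSpec("testes", "captive", 2)])
        cfg = SimulationConfig(
            design=design, coverage_per_amplicon=30,
            conversion_failure_rate=0.0, sequencing_error_rate=0.0, seed=5,
        )
        cohort = simulate_cohort(cfg, materialized_panel)
        matrix = quantify_samples(cohort.sample_reads(), cohort.panel, min_coverage=1)
        # oracle: per sample x amplicon x CpG index, count C/T straight from
        # the read strings using the name-encoded amplicon and mate suffix
        tag_to_amp = {
            a.amplicon_id.replace(" ", ""): a for a in cohort.panel
        }
        oracle: dict[tuple, list[int]] = {}
        for sample, reads in cohort.sample_reads().items():
            for read in reads:
                name, mate = read.id.rsplit("/", 1)
                amp = tag_to_amp[name.split("|")[1]]
                seq = (
                    read.sequence
                    if mate == "1"
                    else reverse_complement(read.sequence)
                )
                offset = 0 if mate == "1" else amp.length - len(seq)
                for i in amp.cpg_indices():
                    j = i - offset
                    if 0 <= j < len(seq):
                        key = (sample, amp.amplicon_id, i)
                        cnt = oracle.setdefault(key, [0, 0])
                        if seq[j] == "C":
                            cnt[0] += 1
                        elif seq[j] == "T":
                            cnt[1] += 1
        for row in matrix.long.itertuples():
            amp = cohort.panel.get(row.amplicon_id)
            i = amp.cpg_indices()[
                [s.position for s in amp.cpg_sites()].index(row.position)
            ]
            c, t = oracle[(row.sample, row.amplicon_id, i)]
            assert (row.count_C, row.count_T) == (c, t)

    def test_conversion_failure_inflates_calls(self, materialized_panel):
        """At true methylation 0, calls inflate by about rate*(100-true)."""
        amp = materialized_panel.get("cyp19a1")
        rate = 0.02
        cfg = SimulationConfig(
            coverage_per_amplicon=5000, conversion_failure_rate=rate,
            sequencing_error_rate=0.0,
        )
        r1, _ = simulate_amplicon_reads(
            "s", amp, np.zeros(amp.declared_cpg_count), cfg, 3
        )
        alns = [bisulfite_align(r, amp, "fwd") for r in r1]
        matrix = call_methylation({"s": alns}, _single_panel(materialized_panel), 100)
        assert matrix.long.pct_meth.mean() == pytest.approx(100 * rate, rel=0.15)

    def test_high_coverage_recovery_within_binomial_bound(self, materialized_panel):
        amp = materialized_panel.get("cyp19a1")
        true = 0.925
        cov = 2000
        cfg = SimulationConfig(
            coverage_per_amplicon=cov, conversion_failure_rate=0.0,
            sequencing_error_rate=0.0,
        )
        r1, r2 = simulate_amplicon_reads(
            "s", amp, np.full(amp.declared_cpg_count, true), cfg, 11
        )
        alns = [bisulfite_align(r, amp, "fwd") for r in r1] + [
            bisulfite_align(r, amp, "rev") for r in r2
        ]
        matrix = call_methylation({"s": alns}, _single_panel(materialized_panel), 100)
        bound = 3 * np.sqrt(true * (1 - true) / cov) * 100
        for pct in matrix.long.pct_meth:
            assert abs(pct - 100 * true) < bound + 1e-9


def test_fastq_round_trip(materialized_panel, tmp_path):
    design = CohortDesign([GroupSpec("ovaries", "wild", 1)])
    cfg = SimulationConfig(design=design, coverage_per_amplicon=3, seed=2)
    cohort = simulate_cohort(cfg, materialized_panel)
    cohort.write_fastq(tmp_path)
    sample = next(iter(cohort.reads))
    back = read_fastq(tmp_path / f"{sample}_R1.fastq.gz")
    orig = cohort.reads[sample][0]
    assert [r.sequence for r in back] == [r.sequence for r in orig]
    assert [r.qualities for r in back] == [r.qualities for r in orig]
    assert all(r.mate == "R2" for r in read_fastq(tmp_path / f"{sample}_R2.fastq.gz"))
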