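"""Group statistics: KW oracle agreement, letters, summaries, density fit."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bsaskit.stats import (
    amplicon_group_summary,
    compact_letter_display,
    compact_letters,
    density_methylation_fit,
    dunn_pairwise,
    kruskal_wallis,
    kruskal_wallis_per_cpg,
    overall_mean,
    panel_density_points,
    round_printed,
    sex_difference_table,
)


def kruskal_wallis_oracle(groups):
    """Brute-force tie-corrected H: average ranks computed by enumeration."""
    pooled = list(itertools.chain.from_iterable(groups))
    n_total = len(pooled)
    order = sorted(range(n_total), key=lambda i: pooled[i])
    ranks = [0.0] * n_total
    i = 0
    while i < n_total:
        j = i
        while j < n_total and pooled[order[j]] == pooled[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    h = 0.0
    pos = 0
    for g in groups:
        r = sum(ranks[pos : pos + len(g)])
        h += r * r / len(g)
        pos += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n_total**3 - n_total)
    return h / correction if correction > 0 else 0.0


class TestOverallMean:
    def test_printed_rows(self):
        assert overall_mean([92.5, 88.0, 44.1, 54.0]) == pytest.approx(69.65)
        assert round_printed(overall_mean([92.5, 88.0, 44.1, 54.0])) == 69.6
        assert round_printed(overall_mean([94.0, 76.6, 59.5, 46.0])) == 69.0

    def test_identical_groups(self):
        assert overall_mean([50.0, 50.0, 50.0, 50.0]) == 50.0


class TestKruskalWallis:
    def test_agrees_with_brute_force_on_small_instances(self, rng):
        """Exhaustive small-case check: 4 groups, n <= 6, integer data (ties)."""
        for _ in range(50):
            sizes = rng.integers(2, 7, size=4)
            groups = [rng.integers(0, 8, size=n).astype(float) for n in sizes]
            if all(np.all(np.concatenate(groups) == groups[0][0]) for _ in [0]):
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_wallis_oracle(groups), abs=1e-9)

    def test_two_group_duplicated_labels(self):
        # {1,2,3} vs {4,5,6} folded into a 4-group call
        groups = [
            np.array([1.0, 2.0]), np.array([3.0]),
            np.array([4.0, 5.0]), np.array([6.0]),
        ]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kruskal_wallis_oracle(groups), abs=1e-12)

    def test_identical_values(self):
        h, p = kruskal_wallis([np.ones(4), np.ones(3), np.ones(5)])
        assert (h, p) == (0.0, 1.0)

    def test_null_type_i_error_rate(self):
        """10,000 null replicates at the study group sizes: rejection ~ alpha."""
        rng = np.random.default_rng(2024)
        sizes = (14, 10, 14, 4)
        alpha = 0.05
        rejections = 0
        reps = 10_000
        for _ in range(reps):
            groups = [rng.normal(size=n) for n in sizes]
            _, p = kruskal_wallis(groups)
            rejections += p < alpha
        assert 0.04 <= rejections / reps <= 0.06


class TestLetters:
    def test_no_significance_shares_a(self, rng):
        vals = {g: rng.normal(0, 1, 8) for g in "abcd"}
        letters = compact_letters(vals, alpha=1e-6)
        assert set(letters.values()) == {"a"}

    def test_separated_group_gets_unique_letter(self, rng):
        vals = {
            "captive_testes": rng.normal(50, 3, 14),
            "wild_testes": rng.normal(50, 3, 10),
            "captive_ovaries": rng.normal(90, 3, 14),
            "wild_ovaries": rng.normal(50, 3, 4),
        }
        letters = compact_letters(vals, alpha=0.05)
        out = letters["captive_ovaries"]
        others = {letters[g] for g in vals if g != "captive_ovaries"}
        assert all(set(out).isdisjoint(set(o)) for o in others)

    def test_relabel_invariance(self, rng):
        data = [rng.normal(m, 2, 10) for m in (10, 10, 40, 70)]
        l1 = compact_letters(dict(zip("abcd", data)))
        l2 = compact_letters(dict(zip("wxyz", data)))
        assert [l1[g] for g in "abcd"] == [l2[g] for g in "wxyz"]

    def test_letters_complement_significance(self, rng):
        """Groups share a letter exactly when not significantly different."""
        for trial in range(10):
            vals = {
                g: rng.normal(rng.uniform(0, 30), 5, 8) for g in "abcd"
            }
            pairs = dunn_pairwise(vals)
            letters = compact_letters(vals, alpha=0.05)
            for row in pairs.itertuples():
                share = bool(set(letters[row.group_a]) & set(letters[row.group_b]))
                assert share == (row.p_adj >= 0.05)

    def test_insertion_algorithm_partition(self):
        letters = compact_letter_display(
            ["a", "b", "c"], {frozenset(("a", "c")), frozenset(("b", "c"))}
        )
        assert set(letters["a"]) & set(letters["b"])
        assert not set(letters["a"]) & set(letters["c"])


def _matrix_from_group_means(group_means, design_sizes, genes=("g",)):
    """Long-form matrix where every sample/CpG carries its group mean."""
    rows = []
    design_rows = []
    for (group, sex), n in design_sizes.items():
        for i in range(n):
            sample = f"{group}_{i:02d}"
            design_rows.append((sample, group, sex, group.split("_")[0]))
            for gene in genes:
                for pos in (10, 20):
                    rows.append(
                        (sample, gene, f"{gene} (1)", pos, 100, 100,
                         0, group_means[group])
                    )
    matrix = pd.DataFrame(
        rows,
        columns=["sample", "gene", "amplicon_id", "position",
                 "count_C", "count_T", "count_other", "pct_meth"],
    )
    design = pd.DataFrame(design_rows, columns=["sample", "group", "sex", "origin"])
    return matrix, design


STUDY_SIZES = {
    ("captive_testes", "testes"): 14,
    ("wild_testes", "testes"): 10,
    ("captive_ovaries", "ovaries"): 14,
    ("wild_ovaries", "ovaries"): 4,
}


class TestAmpliconSummary:
    def test_overall_is_unweighted_group_mean(self):
        means = {
            "captive_testes": 92.5, "wild_testes": 88.0,
            "captive_ovaries": 44.1, "wild_ovaries": 54.0,
        }
        matrix, design = _matrix_from_group_means(means, STUDY_SIZES)
        summary = amplicon_group_summary(matrix, design)
        assert summary.overall_mean.iloc[0] == pytest.approx(69.65)
        for g, m in means.items():
            assert summary[f"{g}_mean"].iloc[0] == pytest.approx(m)

    def test_identical_groups_zero_sd(self):
        means = dict.fromkeys(
            ("captive_testes", "wild_testes", "captive_ovaries", "wild_ovaries"), 50.0
        )
        matrix, design = _matrix_from_group_means(means, STUDY_SIZES)
        summary = amplicon_group_summary(matrix, design)
        assert summary.overall_mean.iloc[0] == 50.0
        assert summary.overall_sd.iloc[0] == 0.0


class TestSexDifference:
    def test_weighting_modes(self):
        means = {
            "captive_testes": 92.5, "wild_testes": 88.0,
            "captive_ovaries": 44.1, "wild_ovaries": 54.0,
        }
        matrix, design = _matrix_from_group_means(means, STUDY_SIZES)
        pooled = sex_difference_table(matrix, design, mode="pooled")
        grouped = sex_difference_table(matrix, design, mode="group_mean")
        # pooled: (14*92.5+10*88)/24 - (14*44.1+4*54)/18
        assert pooled.testes_minus_ovaries.iloc[0] == pytest.approx(44.32, abs=0.01)
        # unweighted group means: 90.25 - 49.05
        assert grouped.testes_minus_ovaries.iloc[0] == pytest.approx(41.2, abs=1e-9)

    def test_identical_sexes_zero(self):
        means = dict.fromkeys(
            ("captive_testes", "wild_testes", "captive_ovaries", "wild_ovaries"), 33.0
        )
        matrix, design = _matrix_from_group_means(means, STUDY_SIZES)
        out = sex_difference_table(matrix, design)
        assert out.testes_minus_ovaries.iloc[0] == 0.0

    def test_antisymmetry_under_label_swap(self):
        means = {
            "captive_testes": 80.0, "wild_testes": 70.0,
            "captive_ovaries": 30.0, "wild_ovaries": 20.0,
        }
        matrix, design = _matrix_from_group_means(means, STUDY_SIZES)
        fwd = sex_difference_table(matrix, design)
        flipped = design.copy()
        flipped["sex"] = flipped.sex.map({"testes": "ovaries", "ovaries": "testes"})
        rev = sex_difference_table(matrix, flipped)
        assert fwd.testes_minus_ovaries.iloc[0] == pytest.approx(
            -rev.testes_minus_ovaries.iloc[0]
        )


class TestPerCpGTests:
    def test_structure_and_letters(self, rng):
        means = {
            "captive_testes": 90.0, "wild_testes": 88.0,
            "captive_ovaries": 30.0, "wild_ovaries": 32.0,
        }
        matrix, design = _matrix_from_group_means(means, STUDY_SIZES)
        # add within-group noise so ranks are informative
        matrix["pct_meth"] += rng.normal(0, 2, size=len(matrix))
        out = kruskal_wallis_per_cpg(matrix, design, alpha=0.05)
        assert len(out) == 2  # two CpG positions
        assert (out.p_value < 0.01).all()
        letters = out.iloc[0]
        assert set(letters.letters_captive_testes).isdisjoint(
            set(letters.letters_captive_ovaries)
        )


class TestDensityFit:
    def test_exact_recovery_noiseless(self):
        x = np.linspace(0.5, 9, 12)
        y = 80.0 * np.exp(-0.5 * x)
        fit = density_methylation_fit(x, y)
        assert fit.a == pytest.approx(80.0, abs=1e-6)
        assert fit.b == pytest.approx(0.5, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_data_b_near_zero(self):
        x = np.linspace(1, 8, 10)
        y = np.full_like(x, 40.0)
        fit = density_methylation_fit(x, y)
        assert abs(fit.b) < 1e-6

    def test_panel_direction_is_decay(self, default_panel):
        """High-density island-like amplicons are hypomethylated: b > 0."""
        overall = {
            amp_id: overall_mean([m for m, _ in groups.values()])
            for amp_id, groups in default_panel.group_methylation.items()
        }
        dens, meth = panel_density_points(default_panel, overall)
        assert len(dens) == 11
        fit = density_methylation_fit(dens, meth)
        assert fit.b > 0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            density_methylation_fit([1.0, 2.0], [3.0, 4.0])
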