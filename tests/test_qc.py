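import numpy as np
import pandas as pd
import pytest

from gbckit import (
    BreedLabels,
    GenotypeMatrix,
    SNPMap,
    filter_reference,
    purity_score,
    select_uniform_snps,
)
from gbckit.synth import BreedSimConfig, CrossSimConfig, simulate_breed_frequencies, simulate_crossbreds


class TestPurityScore:
    def test_concordant_animal_scores_below_cutoff(self):
        # every locus homozygous for the common allele at f = 0.99:
        # P = 0.9801 per locus, score = -2 log10(0.9801) = 0.01746
        y = np.full(100, 2.0)
        f = np.full(100, 0.99)
        ps = purity_score(y, f)
        assert ps.score == pytest.approx(-2 * np.log10(0.9801), abs=1e-10)
        assert ps.score < 2

    def test_discordant_animal_scores_above_cutoff(self):
        # homozygous for the rare allele: P = 0.01^2 per locus, score = 8
        y = np.zeros(50)
        f = np.full(50, 0.99)
        assert purity_score(y, f).score == pytest.approx(8.0)

    def test_locus_order_invariance(self, rng):
        y = rng.integers(0, 3, 200).astype(float)
        f = rng.uniform(0.05, 0.95, 200)
        perm = rng.permutation(200)
        assert purity_score(y, f).score == pytest.approx(
            purity_score(y[perm], f[perm]).score, abs=1e-12
        )

    def test_zero_usable_loci_errors(self):
        with pytest.raises(ValueError, match="usable"):
            purity_score(np.array([np.nan]), np.array([0.5]))

    def test_own_breed_scores_lower_than_migrant(self):
        """An animal drawn from the scored breed's own frequencies scores
        lower than one drawn from a divergent breed in >=95/100 trials."""
        F = simulate_breed_frequencies(BreedSimConfig(M=500, K=2, F=0.4, seed=90))
        f_own, f_other = F.freq[:, 0], F.freq[:, 1]
        wins = 0
        for t in range(100):
            rng = np.random.default_rng(900 + t)
            y_own = rng.binomial(2, f_own).astype(float)
            y_mig = rng.binomial(2, f_other).astype(float)
            if purity_score(y_own, f_own).score < purity_score(y_mig, f_own).score:
                wins += 1
        assert wins >= 95


def _panel_with_migrant(seed=95, n_home=50):
    # two breeds from independent ancestors at high differentiation, so
    # the planted migrant is unambiguously foreign
    from gbckit.containers import AlleleFrequencyTable

    cols = [
        simulate_breed_frequencies(BreedSimConfig(M=800, K=1, F=0.8, seed=seed + k)).freq[:, 0]
        for k in range(2)
    ]
    F = AlleleFrequencyTable(
        [f"snp{i}" for i in range(800)], ["breed1", "breed2"], np.column_stack(cols)
    )
    home = simulate_crossbreds(
        F.subset_breeds(["breed1"]), CrossSimConfig(W=[1.0], n=n_home, seed=seed + 10)
    )
    migrant = simulate_crossbreds(
        F.subset_breeds(["breed2"]), CrossSimConfig(W=[1.0], n=1, seed=seed + 11)
    )
    dosage = np.vstack([home.dosage, migrant.dosage])
    ids = [f"h{i}" for i in range(n_home)] + ["migrant"]
    G = GenotypeMatrix(ids, F.snp_ids, dosage, np.zeros_like(dosage, bool))
    labels = BreedLabels({a: "breed1" for a in ids})
    return G, labels


class TestFilterReference:
    def test_homogeneous_breed_keeps_everyone(self):
        G, labels = _panel_with_migrant()
        G_pure = G.subset_animals([a for a in G.animal_ids if a != "migrant"])
        labels_pure = BreedLabels({a: "breed1" for a in G_pure.animal_ids})
        retained, excluded = filter_reference(G_pure, labels_pure, threshold=2.0)
        assert excluded == []
        assert retained.n_animals == 50

    def test_planted_migrant_is_the_only_exclusion(self):
        G, labels = _panel_with_migrant()
        retained, excluded = filter_reference(G, labels, threshold=2.0)
        assert [p.animal_id for p in excluded] == ["migrant"]
        assert "migrant" not in retained.animal_ids

    def test_infinite_threshold_is_identity(self):
        G, labels = _panel_with_migrant()
        retained, excluded = filter_reference(G, labels, threshold=np.inf)
        assert excluded == []
        assert retained.animal_ids == G.animal_ids

    def test_lower_threshold_excludes_superset(self):
        G, labels = _panel_with_migrant()
        _, ex_tight = filter_reference(G, labels, threshold=0.5)
        _, ex_loose = filter_reference(G, labels, threshold=2.0)
        assert {p.animal_id for p in ex_loose} <= {p.animal_id for p in ex_tight}

    def test_leave_one_out_mode_runs(self):
        G, labels = _panel_with_migrant()
        retained, excluded = filter_reference(G, labels, threshold=2.0, leave_one_out=True)
        assert "migrant" in {p.animal_id for p in excluded}


def _map(positions_by_chrom):
    rows = []
    i = 0
    for chrom, positions in positions_by_chrom.items():
        for p in positions:
            i += 1
            rows.append({"snp_id": f"s{i}", "chrom": chrom, "pos": int(p)})
    return SNPMap(pd.DataFrame(rows))


class TestSelectUniformSNPs:
    def test_requesting_all_returns_all(self):
        m = _map({"1": [1, 2, 3]})
        assert select_uniform_snps(m, 3) == m.snp_ids

    def test_two_from_ten_megabase_grid_hits_endpoints(self):
        m = _map({"1": [i * 1_000_000 for i in range(1, 11)]})
        picked = select_uniform_snps(m, 2)
        pos = m.table.set_index("snp_id").loc[picked, "pos"].tolist()
        assert pos == [1_000_000, 10_000_000]

    def test_too_many_requested_errors(self):
        with pytest.raises(ValueError, match="only"):
            select_uniform_snps(_map({"1": [1, 2]}), 3)

    def test_spacing_bound_on_uniform_map(self):
        rng = np.random.default_rng(42)
        positions = np.sort(rng.choice(np.arange(1, 50_000_000), 400, replace=False))
        m = _map({"1": positions})
        n = 40
        picked = select_uniform_snps(m, n)
        pos = np.sort(m.table.set_index("snp_id").loc[picked, "pos"].to_numpy())
        span = positions.max() - positions.min()
        assert np.diff(pos).max() <= 2 * span / (n - 1)

    def test_output_sorted_and_unique_across_chromosomes(self):
        rng = np.random.default_rng(43)
        m = _map({
            "1": np.sort(rng.choice(np.arange(1, 10_000_000), 50, replace=False)),
            "2": np.sort(rng.choice(np.arange(1, 30_000_000), 150, replace=False)),
        })
        picked = select_uniform_snps(m, 20)
        assert len(picked) == len(set(picked)) == 20
        t = m.table.set_index("snp_id").loc[picked]
        keys = list(zip(t["chrom"], t["pos"]))
        assert keys == sorted(keys)
        # allocation tracks span: chromosome 2 (3x longer) gets more picks
        assert (t["chrom"] == "2").sum() > (t["chrom"] == "1").sum()
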