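"""Load counts, ROH-partitioned homozygote landscape, ratios and sharing."""

import numpy as np
import pandas as pd
import pytest

from mutload import (
    EffectClass,
    GenomeDef,
    PopulationPanel,
    ROHSet,
    VariantTable,
    count_load,
    enrichment,
    enrichment_table,
    partition_load,
    per_length_load,
    ratio_del_syn,
    sharing_spectrum,
)
from mutload.core import MISSING


def make_table(effects, dosage, samples, chrom=None, pos=None):
    n = len(effects)
    return VariantTable(
        chrom=np.array(chrom if chrom is not None else ["LG1"] * n, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, n + 1) * 1000, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        effect=np.array(effects, dtype=object),
        dosage=np.array(dosage, dtype=np.int8),
        samples=samples,
    )


class TestCountLoad:
    def test_hom_and_het_counts_and_allele_total(self):
        # 10 homozygous-derived LoF sites and 4 heterozygous ones
        effects = ["LOF"] * 14
        dosage = [[2]] * 10 + [[1]] * 4
        load = count_load(make_table(effects, dosage, ["i"]))
        row = load.set_index("class").loc["LOF"]
        assert row["n_alleles"] == 24 and row["n_hom"] == 10 and row["n_het"] == 4

    def test_all_ancestral_individual_is_zero(self):
        load = count_load(make_table(["MISSENSE"] * 5, [[0]] * 5, ["i"]))
        row = load.set_index("class").loc["MISSENSE"]
        assert row["n_alleles"] == row["n_hom"] == row["n_het"] == 0

    def test_missing_genotypes_skipped(self):
        load = count_load(
            make_table(["LOF"] * 3, [[2], [MISSING], [1]], ["i"])
        )
        row = load.set_index("class").loc["LOF"]
        assert row["n_callable"] == 2 and row["n_alleles"] == 3

    def test_zero_callable_sites_reported_missing(self):
        load = count_load(make_table(["LOF"], [[MISSING]], ["i"]))
        row = load.set_index("class").loc["LOF"]
        assert np.isnan(row["n_alleles"])

    def test_allele_conservation_on_simulated_panel(self, study_table):
        """n_alleles = 2*n_hom + n_het holds exactly for every individual/class."""
        load = count_load(study_table).dropna()
        assert (load["n_alleles"] == 2 * load["n_hom"] + load["n_het"]).all()


class TestEnrichment:
    def test_all_homozygotes_inside_roh_at_half_coverage(self):
        assert enrichment(10, 10, 0.5) == pytest.approx(2.0)

    def test_zero_homozygotes_in_partition_is_zero(self):
        assert enrichment(0, 10, 0.5) == 0.0

    def test_undefined_cases_are_nan_not_zero(self):
        assert np.isnan(enrichment(0, 0, 0.5))
        assert np.isnan(enrichment(5, 10, 0.0))

    def test_equals_density_ratio_formulation(self):
        """(n_p/n_t)/f_p == (n_p per Mb of partition) / (n_t per Mb of genome)."""
        rng = np.random.default_rng(0)
        G = 50_000_000
        for _ in range(50):
            part_bp = int(rng.integers(1_000_000, G))
            n_t = int(rng.integers(1, 1000))
            n_p = int(rng.integers(0, n_t + 1))
            e = enrichment(n_p, n_t, part_bp / G)
            dens = per_length_load(n_p, part_bp) / per_length_load(n_t, G)
            assert e == pytest.approx(dens, rel=1e-12)

    def test_uniform_homozygote_placement_has_expectation_one(self):
        """Monte-Carlo: random ROH placement over uniformly spread homozygotes."""
        rng = np.random.default_rng(42)
        G, F, n_sites, n_rep = 10_000_000, 0.3, 1000, 60
        genome = GenomeDef({"LG1": G})
        pos = np.sort(rng.choice(np.arange(1, G), n_sites, replace=False))
        vals = []
        for _ in range(n_rep):
            start = int(rng.integers(0, int(G * (1 - F))))
            rs = ROHSet(
                pd.DataFrame(
                    [["i", "LG1", start, start + int(G * F)]],
                    columns=list(ROHSet.COLUMNS),
                )
            )
            table = make_table(
                ["MISSENSE"] * n_sites, [[2]] * n_sites, ["i"], pos=pos
            )
            part = partition_load(table, rs, genome)
            df = enrichment_table(part, genome)
            row = df[(df["class"] == "MISSENSE") & (df["partition"] == "IN_ROH")]
            vals.append(row["enrichment"].iloc[0])
        se = np.sqrt(F * (1 - F) / (n_sites * n_rep)) / F
        assert abs(np.mean(vals) - 1.0) <= 3 * se


class TestPerLength:
    def test_homozygotes_per_mb(self):
        assert per_length_load(30, 15_000_000) == pytest.approx(2.0)
        assert per_length_load(0, 15_000_000) == 0.0

    def test_zero_length_partition_is_nan(self):
        assert np.isnan(per_length_load(3, 0))


class TestPartitionLoad:
    def test_in_plus_out_equals_total(self, study_table, study_sim):
        part = partition_load(
            study_table.subset_sites(study_table.class_mask(EffectClass.LOF)),
            study_sim.truth.roh,
            study_sim.genome,
            classes=(EffectClass.LOF,),
        )
        wide = part.pivot_table(
            index="individual", columns="partition", values="n_hom"
        )
        tot = part.groupby("individual")["n_hom_total"].first()
        assert (wide["IN_ROH"] + wide["OUT_ROH"] == tot).all()
        assert (
            wide["SHORT"] + wide["MEDIUM"] + wide["LONG"] == wide["IN_ROH"]
        ).all()


class TestRatio:
    def _load(self, lof, syn):
        return pd.DataFrame(
            {
                "individual": ["i", "i"],
                "class": ["LOF", "SYNONYMOUS"],
                "n_alleles": [lof, syn],
                "n_hom": [lof, syn],
                "n_het": [lof, syn],
            }
        )

    def test_panel_wide_lof_synonymous_ratio(self):
        r = ratio_del_syn(self._load(994, 70_581), EffectClass.LOF)
        assert r["i"] == pytest.approx(994 / 70_581)

    def test_equal_counts_give_unity(self):
        assert ratio_del_syn(self._load(5, 5), EffectClass.LOF)["i"] == 1.0

    def test_zero_denominator_is_missing(self):
        assert np.isnan(ratio_del_syn(self._load(5, 0), EffectClass.LOF)["i"])

    def test_suppressed_lof_frequencies_reduce_ratio(self, study_sim):
        """LoF/syn allele ratio below missense/syn on the simulated truth."""
        table = study_sim.truth.as_variant_table()
        load = count_load(table)
        lof = ratio_del_syn(load, EffectClass.LOF).mean()
        mis = ratio_del_syn(load, EffectClass.MISSENSE).mean()
        # normalize by the simulated site counts so the comparison reflects
        # per-site frequency suppression rather than class size
        counts = study_sim.config.class_site_counts
        assert lof / (counts["LOF"] / counts["SYNONYMOUS"]) < mis / (
            counts["MISSENSE"] / counts["SYNONYMOUS"]
        )


class TestSharing:
    def make_panel(self, pops):
        rows = []
        for p, inds in pops.items():
            for i in inds:
                rows.append((i, p, "pond", 100.0, 50.0))
        return PopulationPanel(
            pd.DataFrame(
                rows, columns=["individual", "population", "habitat", "ne_hist", "ne_now"]
            )
        )

    def test_private_and_fixed_variants(self):
        panel = self.make_panel({"P1": ["a"], "P2": ["b"], "P3": ["c"]})
        table = make_table(
            ["LOF", "LOF", "LOF"],
            [[1, 0, 0], [2, 2, 2], [0, 0, 0]],
            ["a", "b", "c"],
        )
        spec = sharing_spectrum(table, panel, classes=(EffectClass.LOF,))
        by_k = spec.set_index("k")["proportion"]
        assert by_k[1] == pytest.approx(0.5)  # private variant
        assert by_k[3] == pytest.approx(0.5)  # fixed everywhere
        assert spec["proportion"].sum() == pytest.approx(1.0)

    def test_spectrum_sums_to_one_per_class(self, study_table, study_sim):
        spec = sharing_spectrum(study_table, study_sim.panel)
        sums = spec.groupby("class")["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_needs_two_populations(self):
        panel = self.make_panel({"P1": ["a"]})
        table = make_table(["LOF"], [[1]], ["a"])
        with pytest.raises(ValueError):
            sharing_spectrum(table, panel)
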