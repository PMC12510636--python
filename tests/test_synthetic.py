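"""Synthetic families, proteomes, species sets, and growth curves."""

import math
from collections import Counter

import numpy as np
import pytest

import coconserve as cc
from coconserve.search import parse_header
from coconserve.seqcluster import GAP
from coconserve.synthetic import SpeciesSpec, truth_presence_sheet


def column_identity_to_master(family: cc.Family) -> float:
    """Mean per-member identity to the master, counted column-wise on the
    generated alignment itself (the stated independent check)."""
    master_row = family.msa[0][1]
    idents = []
    for _, row in family.msa[1:]:
        same = total = 0
        for cm, cr in zip(master_row, row):
            if cm != GAP:  # master positions only
                total += 1
                if cr == cm:
                    same += 1
        idents.append(same / total)
    return float(np.mean(idents))


class TestGenerateFamily:
    def test_zero_divergence_gives_identical_gapless_copies(self):
        fam = cc.generate_family(
            cc.FamilySpec(
                gene_name="menB", master_length=50, n_members=5,
                divergence=0.0, indel_rate=0.0, seed=0,
            )
        )
        assert len(fam.members) == 5
        for m in fam.members:
            assert m.residues == fam.master.residues
        assert all(GAP not in row for _, row in fam.msa)

    def test_deterministic_under_fixed_seed(self):
        spec = cc.FamilySpec(gene_name="ubiA", divergence=0.2, seed=1)
        f1, f2 = cc.generate_family(spec), cc.generate_family(spec)
        assert [(m.id, m.residues) for m in f1.members] == [
            (m.id, m.residues) for m in f2.members
        ]
        assert f1.msa == f2.msa

    def test_mean_identity_tracks_divergence(self):
        fam = cc.generate_family(
            cc.FamilySpec(
                gene_name="nuoA", master_length=200, n_members=50,
                divergence=0.2, indel_rate=0.0, seed=5,
            )
        )
        observed = column_identity_to_master(fam)
        assert observed == pytest.approx(math.exp(-0.2), abs=0.03)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"divergence": 1.0},
            {"master_length": 5},
            {"n_members": 0},
            {"indel_rate": 0.5},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        base = dict(gene_name="menB", master_length=50, n_members=3,
                    divergence=0.1, indel_rate=0.0, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            cc.FamilySpec(**base)

    def test_alignment_rows_consistent_and_degap_to_members(self):
        fam = cc.generate_family(
            cc.FamilySpec(
                gene_name="mqnC", master_length=80, n_members=6,
                divergence=0.3, indel_rate=0.05, seed=2,
            )
        )
        width = len(fam.msa[0][1])
        assert all(len(row) == width for _, row in fam.msa)
        by_id = {m.id: m.residues for m in fam.members}
        for rid, row in fam.msa[1:]:
            assert row.replace(GAP, "") == by_id[rid]


class TestGenerateProteome:
    def test_empty_species_yields_empty_proteome_and_false_flags(self, marker_families):
        spec = SpeciesSpec(species_id="sp0", genes_present=frozenset(), n_decoys=0)
        proteomes, truth = cc.generate_proteome(spec, marker_families, seed=0)
        assert list(proteomes) == ["sp0_g1"]
        assert proteomes["sp0_g1"] == []
        assert not any(truth[g] for g in cc.PANEL_GENES)
        assert truth["quinone_category"] == "neither"

    def test_single_gene_with_decoys(self, marker_families):
        spec = SpeciesSpec(
            species_id="sp1", genes_present=frozenset({"ndh"}), n_decoys=10
        )
        proteomes, truth = cc.generate_proteome(spec, marker_families, seed=1)
        records = proteomes["sp1_g1"]
        assert len(records) == 11
        assert truth["ndh2"] and not truth["ndh1"] and not truth["nq"] and not truth["uq"]

    def test_shuffled_decoys_preserve_composition(self, marker_families):
        spec = SpeciesSpec(
            species_id="sp2", genes_present=frozenset(), n_decoys=5
        )
        proteomes, _ = cc.generate_proteome(spec, marker_families, seed=3)
        member_compositions = {
            frozenset(Counter(m.residues).items())
            for fam in marker_families.values()
            for m in fam.members
        }
        for decoy in proteomes["sp2_g1"]:
            assert frozenset(Counter(decoy.residues).items()) in member_compositions

    def test_missing_family_is_configuration_error(self, marker_families):
        families = {g: f for g, f in marker_families.items() if g != "ubiG"}
        spec = SpeciesSpec(species_id="sp3", genes_present=frozenset({"ubiG"}))
        with pytest.raises(KeyError, match="ubiG"):
            cc.generate_proteome(spec, families, seed=0)

    def test_header_dialect_parses_back(self, marker_families):
        spec = SpeciesSpec(
            species_id="spX", genes_present=frozenset({"menB"}), n_decoys=1,
            n_genomes=2,
        )
        proteomes, _ = cc.generate_proteome(spec, marker_families, seed=0)
        for genome_id, records in proteomes.items():
            for r in records:
                g, s = parse_header(r)
                assert (g, s) == (genome_id, "spX")

    def test_genes_outside_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            SpeciesSpec(species_id="sp", genes_present=frozenset({"recA"}))


class TestGenerateSpeciesSet:
    def test_degenerate_distribution(self):
        sset = cc.generate_species_set(
            100, category_freqs={"NQ+NDH2": 1.0}, seed=0
        )
        assert len(sset.truth) == 100
        assert sset.truth["nq"].all()
        assert sset.truth["ndh2"].all()
        assert not sset.truth["uq"].any()

    def test_planted_fraction_within_binomial_bound(self):
        n = 1000
        sset = cc.generate_species_set(
            n,
            category_freqs={"NQ+NDH2": 0.654, "NQ+NDH1": 0.346},
            seed=7,
        )
        nq = sset.truth["nq"]
        assert nq.all()  # every species planted with an NQ variant
        frac = (sset.truth["nq"] & sset.truth["ndh2"]).sum() / n
        sd = math.sqrt(0.654 * 0.346 / n)
        assert abs(frac - 0.654) <= 3 * sd

    def test_truth_flags_equal_pathway_rule_on_genes(self):
        sset = cc.generate_species_set(200, seed=3)
        for _, row in sset.truth.iterrows():
            call = cc.call_pathways({g: bool(row[g]) for g in cc.PANEL_GENES})
            assert call.nq == row["nq"]
            assert call.uq == row["uq"]
            assert call.ndh1 == row["ndh1"]
            assert call.ndh2 == row["ndh2"]
            assert call.quinone_category == row["quinone_category"]
            assert call.dh_category == row["dh_category"]

    def test_deterministic_truth_table(self):
        s1 = cc.generate_species_set(50, seed=9)
        s2 = cc.generate_species_set(50, seed=9)
        assert s1.truth.equals(s2.truth)

    @pytest.mark.parametrize(
        "freqs", [{"NQ+NDH2": 0.5, "UQ+NDH1": 0.4}, {"NQ+NDH2": 1.2, "UQ+NDH1": -0.2}]
    )
    def test_bad_frequencies_rejected(self, freqs):
        with pytest.raises(ValueError):
            cc.generate_species_set(10, category_freqs=freqs, seed=0)

    def test_truth_sheet_layout(self):
        sset = cc.generate_species_set(20, seed=4)
        sheet = truth_presence_sheet(sset)
        assert {"genome_id", "species_id", *cc.PANEL_GENES} <= set(sheet.columns)
        assert len(sheet) == 20


class TestGenerateGrowthCurve:
    def test_exponential_closed_form(self):
        t = np.linspace(0.0, 5.0, 51)
        curve = cc.generate_growth_curve("exponential", mu=0.6, t_grid=t, od0=0.02)
        np.testing.assert_allclose(curve.od600, 0.02 * np.exp(0.6 * t), rtol=1e-12)

    def test_logistic_bounded_and_monotone(self):
        t = np.linspace(0.0, 20.0, 121)
        curve = cc.generate_growth_curve(
            "logistic", mu=0.8, t_grid=t, od0=0.02, K=1.0
        )
        assert (curve.od600 < 1.0).all()
        assert (np.diff(curve.od600) >= 0).all()

    def test_noise_cv_recovered_from_residuals(self):
        t = np.linspace(0.0, 10.0, 200)
        curve = cc.generate_growth_curve(
            "exponential", mu=0.4, t_grid=t, od0=0.05, noise_cv=0.05, seed=21
        )
        clean = 0.05 * np.exp(0.4 * t)
        ratios = curve.od600 / clean
        cv = ratios.std() / ratios.mean()
        assert cv == pytest.approx(0.05, rel=0.30)

    def test_reproducible_and_seed_sensitive(self):
        t = np.linspace(0.0, 5.0, 30)
        kw = dict(mu=0.5, t_grid=t, noise_cv=0.1)
        a = cc.generate_growth_curve("exponential", seed=1, **kw)
        b = cc.generate_growth_curve("exponential", seed=1, **kw)
        c = cc.generate_growth_curve("exponential", seed=2, **kw)
        np.testing.assert_array_equal(a.od600, b.od600)
        assert not np.array_equal(a.od600, c.od600)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cc.generate_growth_curve("exponential", mu=0.5, t_grid=[0.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            cc.generate_growth_curve("logistic", mu=0.5, t_grid=[0.0, 1.0], od0=2.0, K=1.0)
        with pytest.raises(ValueError):
            cc.generate_growth_curve("gompertz", mu=0.5, t_grid=[0.0, 1.0])
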