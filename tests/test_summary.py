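"""Community summaries: profiles, family composition, tracer, screening, viral."""

import numpy as np
import pandas as pd
import pytest

import lithoscreen as ls
from lithoscreen.decontam import OriginCategory
from lithoscreen.errors import ValidationError
from lithoscreen.records import GenomeAnnotation, PcrStatus, SeqStatus
from lithoscreen.summary import _exact_spearman_pvalue


def _call(asv_id, category):
    ev = None
    if category in (OriginCategory.CONTAMINANT,):
        ev = ls.MatchEvidence(asv_id, "ntc", "n1", 1.0)
    return ls.OriginCall(asv_id, category, ev, False, "absent",
                         "R1" if ev else "R3-default")


class TestCategoryAbundance:
    def test_pure_and_mixed_samples(self):
        df = pd.DataFrame({"pure": [100, 0], "mixed": [50, 50]}, index=["a", "b"])
        calls = [
            _call("a", OriginCategory.SUBSURFACE),
            _call("b", OriginCategory.CONTAMINANT),
        ]
        prof = ls.category_abundance(ls.CountTable(df), calls)
        assert prof.loc["pure", "subsurface"] == 1.0
        assert prof.loc["pure", "contaminant"] == 0.0
        assert prof.loc["mixed", "subsurface"] == 0.5
        assert prof.loc["mixed", "contaminant"] == 0.5

    def test_zero_read_sample_flagged_not_divided(self):
        df = pd.DataFrame({"S1": [10], "empty": [0]}, index=["a"])
        prof = ls.category_abundance(
            ls.CountTable(df), [_call("a", OriginCategory.SUBSURFACE)]
        )
        assert prof.loc["empty", "total_reads"] == 0
        assert np.isnan(prof.loc["empty", "subsurface"])

    def test_planted_contaminant_fraction_exact(self):
        df = pd.DataFrame({"S1": [70, 30]}, index=["i", "c"])
        calls = [
            _call("i", OriginCategory.SUBSURFACE),
            _call("c", OriginCategory.CONTAMINANT),
        ]
        prof = ls.category_abundance(ls.CountTable(df), calls)
        assert prof.loc["S1", "contaminant"] == pytest.approx(0.30)


class TestFamilyComposition:
    def _tax(self, asv_id, family=None, phylum=None, order=None):
        ranks = {"family": family, "phylum": phylum, "order": order}
        return ls.TaxonomyAssignment(asv_id, ranks)

    def test_single_family_is_whole_column(self):
        df = pd.DataFrame({"S1": [60], "S2": [40]}, index=["a"])
        fam = ls.family_composition(
            ls.CountTable(df), {"a": self._tax("a", family="Halomonadaceae")}
        )
        assert list(fam.index) == ["Halomonadaceae"]
        assert (fam.loc["Halomonadaceae"] == 1.0).all()

    def test_rare_family_collapses_to_other(self):
        df = pd.DataFrame({"S1": [9995, 5]}, index=["a", "b"])  # b at 0.05%
        tax = {
            "a": self._tax("a", family="BigFam"),
            "b": self._tax("b", family="TinyFam"),
        }
        fam = ls.family_composition(ls.CountTable(df), tax, 0.001)
        assert "TinyFam" not in fam.index
        assert fam.loc["other family", "S1"] == pytest.approx(0.0005)
        assert fam["S1"].sum() == pytest.approx(1.0)

    def test_phylum_fallback_label(self):
        df = pd.DataFrame({"S1": [10]}, index=["a"])
        fam = ls.family_composition(
            ls.CountTable(df), {"a": self._tax("a", phylum="Chloroflexi")}
        )
        assert list(fam.index) == ["(p) Chloroflexi"]

    def test_missing_taxonomy_goes_to_unknown(self, caplog):
        df = pd.DataFrame({"S1": [10]}, index=["a"])
        with caplog.at_level("WARNING"):
            fam = ls.family_composition(ls.CountTable(df), {})
        assert list(fam.index) == ["unknown bacteria"]
        assert "missing taxonomy" in caplog.text

    def test_columns_sum_to_one(self, community, calls):
        _, com, table = community
        filtered = ls.filter_contaminants(table, calls).table
        tax = {
            a: ls.TaxonomyAssignment(a, {"family": f"Fam{i % 4}"})
            for i, a in enumerate(filtered.asv_ids)
        }
        fam = ls.family_composition(filtered, tax)
        nonzero = filtered.df.sum(axis=0) > 0
        assert np.allclose(fam.loc[:, nonzero].sum(axis=0), 1.0)


def _sample(sid, pfc, pcr="+", seq=None, lith="basalt"):
    pcr_status = {"+": PcrStatus.POSITIVE, "-": PcrStatus.NEGATIVE,
                  "nc": PcrStatus.NO_CELLS}[pcr]
    if seq is None:
        seq_status = (SeqStatus.NOT_APPLICABLE if pcr == "nc" else SeqStatus.FAILED)
    else:
        seq_status = seq
    return ls.SampleRecord(
        sample_id=sid, lithology=lith, depth_mbsf=1.0, cell_density=100.0,
        pcr_status=pcr_status, seq_status=seq_status,
        pfc_interior=pfc, pfc_exterior=ls.records.Sentinel("BDL"),
    )


class TestTracerComparison:
    def _profiles(self, indigenous):
        return pd.DataFrame({
            "subsurface": indigenous,
            "possibly_subsurface": [0.0] * len(indigenous),
            "likely_contaminant": [0.0] * len(indigenous),
            "contaminant": [1 - x for x in indigenous],
            "total_reads": [1000] * len(indigenous),
        }, index=[f"S{i}" for i in range(len(indigenous))])

    def test_antimonotone_construction_gives_minus_one(self):
        indigenous = [0.9, 0.7, 0.5, 0.3, 0.1]
        tracer = [1.0, 10.0, 100.0, 1000.0, 10000.0]
        samples = [_sample(f"S{i}", t) for i, t in enumerate(tracer)]
        rep = ls.tracer_comparison(self._profiles(indigenous), samples)
        assert rep["status"] == "ok"
        assert rep["rank_correlation"] == pytest.approx(-1.0)
        # exact two-sided permutation p for perfect anti-correlation: 2/5!
        assert rep["p_method"] == "exact_permutation"
        assert rep["p_value"] == pytest.approx(2 / 120)

    def test_all_bdl_insufficient(self):
        samples = [_sample(f"S{i}", ls.records.Sentinel("BDL")) for i in range(5)]
        rep = ls.tracer_comparison(self._profiles([0.9, 0.7, 0.5, 0.3, 0.1]), samples)
        assert rep["status"] == "insufficient_data"
        assert rep["n_excluded"] == 5

    def test_order_invariance(self):
        indigenous = [0.9, 0.7, 0.5, 0.2]
        samples = [_sample(f"S{i}", 10.0 ** i) for i in range(4)]
        rep1 = ls.tracer_comparison(self._profiles(indigenous), samples)
        rep2 = ls.tracer_comparison(self._profiles(indigenous), samples[::-1])
        assert rep1 == rep2

    def test_exact_pvalue_matches_brute_force_enumeration(self):
        """Oracle: direct 5! enumeration with scipy's spearman rho per pairing."""
        import itertools
        from scipy import stats
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        observed = abs(stats.spearmanr(x, y).statistic)
        hits = sum(
            abs(stats.spearmanr(x, y[list(p)]).statistic) >= observed - 1e-12
            for p in itertools.permutations(range(5))
        )
        assert _exact_spearman_pvalue(x, y) == pytest.approx(hits / 120, abs=1e-12)


class TestScreening:
    def test_reference_table_counts(self):
        s = ls.summarize_screening(ls.reference_sample_table())
        assert s.n_screened == 29
        assert s.n_cells_detected == 18
        assert s.n_sequenced == 8
        assert s.n_sequenced_sediment == 3
        assert s.n_sequenced_crust == 5
        assert s.to_dict()["efficiency_percent_display"] == 28.0

    def test_counts_stable_under_permutation_and_chain(self):
        samples = ls.reference_sample_table()
        s1 = ls.summarize_screening(samples)
        s2 = ls.summarize_screening(samples[::-1])
        assert s1 == s2
        assert (
            s1.n_sequenced <= s1.n_pcr_positive
            <= s1.n_cells_detected <= s1.n_screened
        )

    def test_empty_list_errors(self):
        with pytest.raises(ValidationError):
            ls.summarize_screening([])


class TestViralEvidence:
    def _genomes(self, n_mag, n_mag_viral, n_sag, n_sag_viral):
        gs = []
        for i in range(n_mag):
            gs.append(GenomeAnnotation(f"mag{i}", "MAG", {},
                                       has_viral_evidence=i < n_mag_viral))
        for i in range(n_sag):
            gs.append(GenomeAnnotation(f"sag{i}", "SAG", {},
                                       has_viral_evidence=i < n_sag_viral))
        return gs

    def test_published_counts_give_26_percent(self):
        """9/33 MAGs + 60/227 SAGs -> 69/260 ~ 26.5% combined."""
        out = ls.summarize_viral_evidence(self._genomes(33, 9, 227, 60))
        assert out["MAG"]["n_viral"] == 9
        assert out["SAG"]["n_viral"] == 60
        assert out["combined"]["fraction"] == pytest.approx(69 / 260)
        assert out["combined"]["percent_display"] == 26.5

    @pytest.mark.parametrize("flagged,expected", [(0, 0.0), (5, 1.0)])
    def test_extremes(self, flagged, expected):
        out = ls.summarize_viral_evidence(self._genomes(5, flagged, 0, 0))
        assert out["combined"]["fraction"] == expected
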