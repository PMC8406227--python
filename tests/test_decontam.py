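"""The four-category origin classifier: rule cascade, filtering, invariants."""

import numpy as np
import pandas as pd
import pytest

import lithoscreen as ls
from lithoscreen.decontam import (
    CATEGORY_ORDER,
    ClassifierParams,
    OriginCategory,
    calls_to_frame,
)
from lithoscreen.errors import ValidationError
from lithoscreen.similarity import IdentityParams

from conftest import mutate, random_dna


def _setup_rules():
    """A 4-ASV scenario exercising R1, R2-subsurface, R3-subsurface, R3-default."""
    rng = np.random.default_rng(10)
    ntc_seq = random_dna(rng, 300)
    sea_seq = random_dna(rng, 300)
    free1 = random_dna(rng, 300)
    free2 = random_dna(rng, 300)
    asvs = {
        "a_r1": ls.SequenceRecord("a_r1", ntc_seq),
        "a_r2": ls.SequenceRecord("a_r2", mutate(sea_seq, [10, 200])),  # 0.9933 to sw
        "a_r3s": ls.SequenceRecord("a_r3s", free1),
        "a_r3d": ls.SequenceRecord("a_r3d", free2),
    }
    controls = ls.ControlCollection(
        ntc=[ls.SequenceRecord("n1", ntc_seq)],
        seawater=[ls.SequenceRecord("sw1", sea_seq)],
    )
    wl = ls.Whitelist([ls.SequenceRecord("w1", asvs["a_r2"].sequence)], "exact_sequence")
    env = {
        "a_r2": "serpentinite-hosted subsurface clone",
        "a_r3s": "terrestrial subsurface aquifer",
    }
    df = pd.DataFrame(
        {"S1": [100, 100, 100, 100]}, index=["a_r1", "a_r2", "a_r3s", "a_r3d"]
    )
    return ls.CountTable(df), asvs, controls, wl, env


class TestRuleCascade:
    def test_four_rules_compose(self):
        table, asvs, controls, wl, env = _setup_rules()
        calls = ls.classify_table(table, asvs, controls, wl, env)
        got = {c.asv_id: (c.category, c.rule_fired) for c in calls}
        assert got["a_r1"] == (OriginCategory.CONTAMINANT, "R1")
        assert got["a_r2"] == (OriginCategory.POSSIBLY_SUBSURFACE, "R2-subsurface")
        assert got["a_r3s"] == (OriginCategory.SUBSURFACE, "R3-subsurface")
        assert got["a_r3d"] == (OriginCategory.POSSIBLY_SUBSURFACE, "R3-default")

    def test_no_blast_hit_takes_default_policy(self):
        table, asvs, controls, wl, _ = _setup_rules()
        call = ls.classify_asv(asvs["a_r3d"], 100, controls, wl, "absent")
        assert call.category is OriginCategory.POSSIBLY_SUBSURFACE
        assert call.env_class == "absent"

    def test_unknown_env_policies_configurable(self):
        table, asvs, controls, wl, _ = _setup_rules()
        params = ClassifierParams(
            unknown_env_policy_unmatched=OriginCategory.LIKELY_CONTAMINANT
        )
        call = ls.classify_asv(asvs["a_r3d"], 100, controls, wl, "absent", params)
        assert call.category is OriginCategory.LIKELY_CONTAMINANT

    def test_whitelisted_never_hard_contaminant(self):
        """The whitelist exception: a control match alone cannot condemn."""
        table, asvs, controls, wl, env = _setup_rules()
        calls = ls.classify_table(table, asvs, controls, wl, env)
        for c in calls:
            if c.whitelisted:
                assert c.category is not OriginCategory.CONTAMINANT

    def test_empty_controls_with_whitelist_r1_unreachable(self):
        table, asvs, _, wl, env = _setup_rules()
        calls = ls.classify_table(table, asvs, ls.ControlCollection(), wl, env)
        assert all(c.category is not OriginCategory.CONTAMINANT for c in calls)

    def test_all_ntc_copies_without_whitelist_all_contaminant(self):
        rng = np.random.default_rng(11)
        seqs = [random_dna(rng, 200) for _ in range(3)]
        asvs = {f"a{i}": ls.SequenceRecord(f"a{i}", s) for i, s in enumerate(seqs)}
        controls = ls.ControlCollection(
            ntc=[ls.SequenceRecord(f"n{i}", s) for i, s in enumerate(seqs)]
        )
        df = pd.DataFrame({"S1": [10, 20, 30]}, index=list(asvs))
        calls = ls.classify_table(ls.CountTable(df), asvs, controls, None, None)
        assert all(c.category is OriginCategory.CONTAMINANT for c in calls)

    def test_no_evidence_basis_is_hard_error(self):
        rec = ls.SequenceRecord("a", "ACGT" * 20)
        with pytest.raises(ValidationError, match="no evidence basis"):
            ls.classify_asv(rec, 10, ls.ControlCollection(), None, "absent")

    def test_missing_sequence_names_asv(self):
        table, asvs, controls, wl, env = _setup_rules()
        del asvs["a_r3d"]
        with pytest.raises(ValidationError, match="a_r3d"):
            ls.classify_table(table, asvs, controls, wl, env)

    def test_abundance_gate_suppresses_env_below_cutoff(self):
        """Below the read gate, environment evidence is not consulted."""
        table, asvs, controls, wl, env = _setup_rules()
        params = ClassifierParams(abundance_gate_reads=5000)
        calls = ls.classify_table(table, asvs, controls, wl, env, params=params)
        got = {c.asv_id: c for c in calls}
        # a_r3s has subsurface-like env but only 100 reads -> default branch
        assert got["a_r3s"].category is OriginCategory.POSSIBLY_SUBSURFACE
        assert got["a_r3s"].rule_fired == "R3-default"
        # R1 does not depend on environment and is unaffected
        assert got["a_r1"].category is OriginCategory.CONTAMINANT


class TestInvariants:
    def test_partition_exactly_one_category(self, community, calls):
        _, _, table = community
        assert len(calls) == len(table.asv_ids)
        profiles = ls.category_abundance(table, calls)
        frac = profiles[[c.value for c in CATEGORY_ORDER]]
        sums = frac.sum(axis=1)
        nonzero = profiles["total_reads"] > 0
        assert np.allclose(sums[nonzero], 1.0, atol=1e-9)

    def test_determinism_byte_identical(self, community, calls):
        _, com, table = community
        seqs = {a.id: a for a in com.asvs}
        again = ls.classify_table(
            table, seqs, com.controls, com.whitelist, com.environment
        )
        assert calls_to_frame(calls).equals(calls_to_frame(again))

    def test_filter_conservation(self, community, calls):
        _, _, table = community
        res = ls.filter_contaminants(table, calls)
        assert (res.table.df.values <= table.df.loc[res.table.asv_ids].values).all().all()
        removed = table.df.sum().sum() - res.table.df.sum().sum()
        dropped = set(table.asv_ids) - set(res.table.asv_ids)
        assert removed == table.df.loc[sorted(dropped)].sum().sum()

    def test_threshold_monotonic_category_flow(self, community):
        """Lowering the identity threshold only moves mass toward contamination."""
        _, com, table = community
        seqs = {a.id: a for a in com.asvs}
        matched_prev = None
        for thr in (0.999, 0.97, 0.90):
            params = ClassifierParams(identity=IdentityParams(threshold=thr))
            calls = ls.classify_table(
                table, seqs, com.controls, com.whitelist, com.environment, params=params
            )
            matched = {c.asv_id for c in calls if c.control_evidence is not None}
            if matched_prev is not None:
                assert matched_prev <= matched
            matched_prev = matched


class TestFilter:
    def test_identity_when_no_contaminants(self):
        df = pd.DataFrame({"S1": [5, 5]}, index=["a", "b"])
        table = ls.CountTable(df)
        calls = [
            ls.OriginCall("a", OriginCategory.POSSIBLY_SUBSURFACE, None, False, "absent", "R3-default"),
            ls.OriginCall("b", OriginCategory.SUBSURFACE, None, False, "subsurface_like", "R3-subsurface"),
        ]
        res = ls.filter_contaminants(table, calls)
        assert res.table == table
        assert not res.report["fully_excluded"].any()

    def test_fully_excluded_sample_flagged(self, community, calls):
        """A sample whose reads all sit on contaminant ASVs is reported excluded."""
        _, _, table = community
        res = ls.filter_contaminants(table, calls)
        rep = res.report.set_index("sample_id")
        assert bool(rep.loc["S8", "fully_excluded"])  # planted fraction 1.0
        assert not rep.loc["S1", "fully_excluded"]  # planted fraction 0.0
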