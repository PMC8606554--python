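import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pfsmeta.dataset import (
    Arm,
    ArmObservation,
    Corpus,
    CorpusValidationError,
    CovariateProfile,
    SchemaError,
    group_totals,
    read_corpus,
    summarize_corpus,
    write_corpus,
)
from pfsmeta.fitting import residual_se


def _mono_profile(**kw):
    base = dict(therapy_type="monotherapy", drug="olaparib", biomarker="BRCAm")
    base.update(kw)
    return CovariateProfile(**base)


def _write_rows(tmp_path, rows, name="c.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _row(study="S1", arm="A", n=100, time=3.0, frac=0.9, **kw):
    base = dict(study_id=study, arm_id=arm, n=n, therapy_type="monotherapy",
                drug="olaparib", biomarker="BRCAm", platinum="sensitive",
                partner="none", time_months=time, surv_fraction=frac)
    base.update(kw)
    return base


class TestReadCorpus:
    def test_two_row_single_arm(self, tmp_path):
        path = _write_rows(tmp_path, [_row(time=3, frac=0.9), _row(time=6, frac=0.7)])
        corpus = read_corpus(path)
        assert len(corpus.studies) == 1 and len(corpus.arms) == 1
        obs = corpus.arms[0].observations
        assert [o.time for o in obs] == [3.0, 6.0]
        assert obs[0].se == pytest.approx(math.sqrt(0.9 * 0.1 / 100), abs=1e-15)

    def test_fraction_out_of_range_rejected(self, tmp_path):
        path = _write_rows(tmp_path, [_row(frac=1.2)])
        with pytest.raises(CorpusValidationError):
            read_corpus(path)

    def test_missing_column_named_in_error(self, tmp_path):
        rows = [_row()]
        for r in rows:
            del r["surv_fraction"]
        path = _write_rows(tmp_path, rows)
        with pytest.raises(SchemaError, match="surv_fraction"):
            read_corpus(path)

    def test_duplicate_time_rejected(self, tmp_path):
        path = _write_rows(tmp_path, [_row(time=3, frac=0.9), _row(time=3, frac=0.8)])
        with pytest.raises(CorpusValidationError):
            read_corpus(path)

    def test_schema_renaming(self, tmp_path):
        rows = [_row()]
        df = pd.DataFrame(rows).rename(columns={"surv_fraction": "pfs_rate"})
        path = tmp_path / "renamed.csv"
        df.to_csv(path, index=False)
        corpus = read_corpus(path, schema={"surv_fraction": "pfs_rate"})
        assert corpus.arms[0].observations[0].obs_fraction == 0.9


class TestWriteCorpus:
    def test_round_trip_identity(self, tmp_path, ref_corpus):
        corpus, _ = ref_corpus
        path = tmp_path / "rt.csv"
        write_corpus(corpus, path)
        back = read_corpus(path)
        assert len(back.arms) == len(corpus.arms)
        for a, b in zip(corpus.arms, back.arms):
            assert (a.study_id, a.arm_id, a.n) == (b.study_id, b.arm_id, b.n)
            assert a.covariates == b.covariates
            assert np.allclose(a.times, b.times)
            assert np.allclose(a.fractions, b.fractions)
            for oa, ob in zip(a.observations, b.observations):
                assert oa.se == pytest.approx(ob.se, abs=1e-12)

    def test_row_count_is_total_observations(self, tmp_path, ref_corpus):
        corpus, _ = ref_corpus
        path = tmp_path / "rows.csv"
        write_corpus(corpus, path)
        assert len(pd.read_csv(path)) == corpus.n_observations

    def test_empty_arm_refused(self, tmp_path):
        corpus = Corpus(arms=[Arm("S1", "A", 10, _mono_profile(), [])])
        with pytest.raises(CorpusValidationError):
            write_corpus(corpus, tmp_path / "bad.csv")


@st.composite
def corpora(draw):
    n_studies = draw(st.integers(1, 3))
    arms = []
    for s in range(n_studies):
        for a in range(draw(st.integers(1, 2))):
            n = draw(st.integers(5, 400))
            m = draw(st.integers(1, 5))
            times = sorted(draw(st.sets(st.integers(1, 48), min_size=m, max_size=m)))
            fracs = [round(draw(st.floats(0.0, 1.0)), 6) for _ in times]
            obs = [
                ArmObservation(time=float(t), obs_fraction=f,
                               se=residual_se(f, n))
                for t, f in zip(times, fracs)
            ]
            combo = draw(st.booleans())
            prof = CovariateProfile(
                therapy_type="combination" if combo else "monotherapy",
                drug=draw(st.sampled_from(["olaparib", "niraparib", "rucaparib"])),
                biomarker=draw(st.sampled_from(["BRCAm", "BRCAwt", "HRD_positive"])),
                partner="bevacizumab" if combo else "none",
                ecog0_pct=draw(st.one_of(st.none(), st.floats(0, 100))),
            )
            arms.append(Arm(f"S{s}", f"A{a}", n, prof, obs))
    return Corpus(arms=arms)


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(corpora())
    def test_round_trip_lossless(self, tmp_path_factory, corpus):
        path = tmp_path_factory.mktemp("rt") / "c.csv"
        write_corpus(corpus, path)
        back = read_corpus(path)
        for a, b in zip(corpus.arms, back.arms):
            assert a.covariates == b.covariates
            assert np.allclose(a.times, b.times)
            assert np.allclose(a.fractions, b.fractions)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(corpora())
    def test_se_matches_binomial_formula(self, corpus):
        for arm in corpus.arms:
            for o in arm.observations:
                assert o.se == pytest.approx(
                    residual_se(o.obs_fraction, arm.n), abs=1e-12
                )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(corpora())
    def test_group_totals_partition_grand_total(self, corpus):
        table = summarize_corpus(corpus)
        for dim in ("drug", "biomarker", "therapy_type", "platinum"):
            sub = table[table["dimension"] == dim]
            assert sub["patients"].sum() == corpus.n_patients


class TestSummarize:
    def test_single_arm_totals_zero_or_n(self):
        corpus = Corpus(arms=[Arm("S1", "A", 50, _mono_profile(), [
            ArmObservation(time=3.0, obs_fraction=0.8, se=residual_se(0.8, 50))
        ])])
        for total in summarize_corpus(corpus)["patients"]:
            assert total in (0, 50)

    def test_disjoint_corpora_totals_add(self, ref_corpus):
        corpus, _ = ref_corpus
        half1 = Corpus(arms=corpus.arms[:6])
        half2 = Corpus(arms=corpus.arms[6:])
        merged = Corpus(arms=corpus.arms)
        for dim in ("drug", "biomarker"):
            t1, t2, tm = (group_totals(c, dim) for c in (half1, half2, merged))
            for level, total in tm.items():
                assert t1.get(level, 0) + t2.get(level, 0) == total


class TestProfileInvariants:
    def test_partner_therapy_consistency_enforced(self):
        with pytest.raises(CorpusValidationError):
            CovariateProfile(therapy_type="monotherapy", drug="olaparib",
                             biomarker="BRCAm", partner="bevacizumab")
        with pytest.raises(CorpusValidationError):
            CovariateProfile(therapy_type="combination", drug="olaparib",
                             biomarker="BRCAm", partner="none")

    def test_unknown_level_rejected(self):
        with pytest.raises(CorpusValidationError):
            CovariateProfile(therapy_type="monotherapy", drug="aspirin",
                             biomarker="BRCAm")
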