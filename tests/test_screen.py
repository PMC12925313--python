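"""Genome quality filtering, domtblout parsing and presence calling."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycopan import screen
from glycopan.screen import (
    CheckmRecord,
    DomtblParseError,
    GeneHit,
    InvalidRecordError,
    ProfileMeta,
)


def _hit(genome="g1", family="K1", orf="orf1", bitscore=100.0, evalue=1e-50,
         span=(0, 180), plen=200):
    return GeneHit(genome, family, orf, bitscore, evalue, span, plen)


class TestFilterGenomes:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (95.0, 2.0, True),   # both bounds satisfied
            (89.9, 2.0, False),  # below completeness cutoff
            (95.0, 5.1, False),  # above contamination cutoff
            (90.0, 5.0, True),   # boundary values retained
            (50.0, 1.0, False),  # either bound violated removes
        ],
    )
    def test_bounds(self, completeness, contamination, kept):
        recs = [CheckmRecord("g", completeness, contamination)]
        got = screen.filter_genomes(recs)
        assert (got == ["g"]) is kept

    def test_invalid_record_names_genome(self):
        with pytest.raises(InvalidRecordError, match="gX"):
            screen.filter_genomes([CheckmRecord("gX", 95.0, -1.0)])
        with pytest.raises(InvalidRecordError, match="gY"):
            screen.filter_genomes([CheckmRecord("gY", 101.0, 0.0)])

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 50)),
                    min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_idempotent_and_order_preserving(self, qualities):
        recs = [CheckmRecord(f"g{i}", c, x) for i, (c, x) in enumerate(qualities)]
        kept = screen.filter_genomes(recs)
        if kept:
            again = screen.filter_genomes(
                [r for r in recs if r.genome_id in set(kept)])
            assert kept == again
        assert kept == [r.genome_id for r in recs if r.genome_id in set(kept)]


class TestParseDomtbl:
    HEADER = "# comment line\n#\n"
    LINE = ("{orf} - 350 {fam} - 200 1e-50 250.0 0.1 1 1 "
            "1e-50 1e-50 250.0 0.1 {hf} {ht} 10 190 5 195 0.95 desc")

    def _stream(self, lines):
        return io.StringIO(self.HEADER + "\n".join(lines) + "\n")

    def test_counts_and_comments(self):
        lines = [self.LINE.format(orf=f"g1|o{i}", fam="K1", hf=11, ht=190)
                 for i in range(3)]
        hits = screen.parse_domtbl(self._stream(lines))
        assert len(hits) == 3
        assert screen.parse_domtbl(io.StringIO(self.HEADER)) == []

    def test_truncated_line_reports_lineno(self):
        with pytest.raises(DomtblParseError, match="line 3"):
            screen.parse_domtbl(self._stream(["g1|o1 - 350 K1"]))

    def test_domain_union_coverage(self):
        # two domains of one ORF: spans [11,100] and [51,190] union to 180
        lines = [self.LINE.format(orf="g1|o1", fam="K1", hf=11, ht=100),
                 self.LINE.format(orf="g1|o1", fam="K1", hf=51, ht=190)]
        (hit,) = screen.parse_domtbl(self._stream(lines))
        assert hit.coverage == pytest.approx(180 / 200)


class TestApplyThresholds:
    PROFILES = {
        "K1": ProfileMeta("K1", None, 500),
        "K2": ProfileMeta("K2", 100.0, 500),
    }

    @pytest.mark.parametrize(
        "family,bitscore,evalue,cover,kept",
        [
            ("K1", 50.0, 1e-21, 0.80, True),   # fallback rule satisfied
            ("K1", 50.0, 1e-19, 0.90, False),  # e-value above cutoff
            ("K1", 50.0, 1e-21, 0.70, False),  # coverage below cutoff
            ("K2", 120.0, 1.0, 0.10, True),    # curated threshold only
            ("K2", 99.9, 1e-80, 0.99, False),  # below curated threshold
        ],
    )
    def test_rules(self, family, bitscore, evalue, cover, kept):
        h = _hit(family=family, bitscore=bitscore, evalue=evalue,
                 span=(0, int(cover * 200)))
        got = screen.apply_thresholds([h], self.PROFILES)
        assert (got == [h]) is kept

    def test_unknown_family_errors(self):
        with pytest.raises(KeyError, match="K9"):
            screen.apply_thresholds([_hit(family="K9")], self.PROFILES)

    def test_permissive_settings_are_identity(self):
        hits = [_hit(orf=f"o{i}", evalue=10.0 ** -i, span=(0, i * 20))
                for i in range(5)]
        profiles = {"K1": ProfileMeta("K1", None, 500)}
        got = screen.apply_thresholds(hits, profiles,
                                      fallback_evalue=float("inf"),
                                      min_query_cover=0.0)
        assert got == hits


def test_exclude_small_families_strict_boundary():
    profiles = {n: ProfileMeta(n, None, s)
                for n, s in [("a", 199), ("b", 200), ("c", 5000)]}
    kept = screen.exclude_small_families(profiles, min_seqs=200)
    assert set(kept) == {"b", "c"}
    assert screen.exclude_small_families(profiles, min_seqs=0) == profiles


class TestBestHit:
    def test_highest_bitscore_wins(self):
        hits = [_hit(orf="a", bitscore=50), _hit(orf="b", bitscore=70)]
        assert [h.orf_id for h in screen.best_hit_per_family(hits)] == ["b"]

    def test_tie_breaks_evalue_then_orf(self):
        hits = [_hit(orf="z", bitscore=70, evalue=1e-25),
                _hit(orf="a", bitscore=70, evalue=1e-30)]
        assert screen.best_hit_per_family(hits)[0].orf_id == "a"
        hits = [_hit(orf="z", bitscore=70), _hit(orf="a", bitscore=70)]
        assert screen.best_hit_per_family(hits)[0].orf_id == "a"

    def test_single_hit_is_itself(self):
        h = _hit()
        assert screen.best_hit_per_family([h]) == [h]


class TestPresenceMatrix:
    def test_basic_and_zero_rows(self):
        m = screen.build_presence_matrix([_hit()], ["g1", "g2"], ["K1"])
        assert m.values.tolist() == [[1], [0]]
        empty = screen.build_presence_matrix([], ["g1"], ["K1"])
        assert empty.values.sum() == 0

    def test_duplicates_and_row_order_invariance(self):
        hits = [_hit(orf="a"), _hit(orf="b"), _hit(genome="g2", family="K2")]
        m1 = screen.build_presence_matrix(hits, ["g1", "g2"], ["K1", "K2"])
        m2 = screen.build_presence_matrix(hits[::-1], ["g1", "g2"], ["K1", "K2"])
        pd.testing.assert_frame_equal(m1, m2)
        assert m1.loc["g1", "K1"] == 1


class TestGenePrevalence:
    def test_core_boundary_61_genomes(self):
        def matrix(n_present):
            col = [1] * n_present + [0] * (61 - n_present)
            return pd.DataFrame({"K1": col}, index=[f"g{i}" for i in range(61)])

        assert screen.classify_gene_prevalence(matrix(55))["label"]["K1"] == "core"
        assert (screen.classify_gene_prevalence(matrix(54))["label"]["K1"]
                == "accessory")
        assert screen.classify_gene_prevalence(matrix(0))["label"]["K1"] == "absent"

    @given(st.integers(0, 20), st.floats(0.1, 1.0), st.floats(0.1, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_raising_threshold_never_promotes(self, n_present, f1, f2):
        lo, hi = sorted([f1, f2])
        col = [1] * n_present + [0] * (20 - n_present)
        m = pd.DataFrame({"K1": col}, index=[f"g{i}" for i in range(20)])
        lab_lo = screen.classify_gene_prevalence(m, lo)["label"]["K1"]
        lab_hi = screen.classify_gene_prevalence(m, hi)["label"]["K1"]
        assert not (lab_lo == "accessory" and lab_hi == "core")


def test_select_marker_genomes_best_orf():
    hits = [_hit(genome="g1", family="KM", orf="low", bitscore=100),
            _hit(genome="g1", family="KM", orf="high", bitscore=300),
            _hit(genome="g2", family="K1")]
    got = screen.select_marker_genomes(hits, "KM")
    assert got == {"g1": "high"}
    assert screen.select_marker_genomes([], "KM") == {}
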