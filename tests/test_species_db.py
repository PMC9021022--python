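"""Tests of SDB parsing, filtering, scenario resolution and age sampling."""

import numpy as np
import pytest

import paleohabitat as ph
from paleohabitat.species_db import (
    AGE_WINDOW_KA,
    canonical_species,
    records_to_frame,
    summarize,
)

from conftest import make_record

CSV_HEADER = "site_name,layer_id,lon,lat,age_ka,age_uncertainty_ka,species,dating_method,region\n"


def write_csv(tmp_path, rows, header=CSV_HEADER):
    path = tmp_path / "sdb.csv"
    path.write_text(header + "\n".join(rows) + "\n")
    return path


class TestParse:
    def test_well_formed_rows_parse_cleanly(self, tmp_path):
        path = write_csv(
            tmp_path,
            [
                "Olduvai,Bed I,35.35,-2.99,1800,50,H. habilis,Ar/Ar,Africa",
                "Atapuerca,TD6,-3.52,42.35,850,70,Homo heidelbergensis,ESR,Europe",
                "Vindija,G1,16.08,46.30,44,2,neanderthalensis;sapiens,14C,Europe",
            ],
        )
        res = ph.parse_sdb(path)
        assert len(res.records) == 3 and len(res.rejects) == 0
        assert res.records[0].attributions == ("habilis",)
        assert res.records[2].attributions == ("neanderthalensis", "sapiens")

    def test_blank_uncertainty_defaults_to_zero(self, tmp_path, caplog):
        path = write_csv(tmp_path, ["A,,10,10,100,,sapiens,14C,"])
        with caplog.at_level("WARNING"):
            res = ph.parse_sdb(path)
        assert res.records[0].age_uncertainty_ka == 0.0
        assert any("blank age uncertainty" in m for m in caplog.messages)

    def test_bad_latitude_routed_to_rejects(self, tmp_path):
        path = write_csv(
            tmp_path,
            ["A,,10,95,100,5,sapiens,14C,", "B,,10,10,100,5,sapiens,14C,"],
        )
        res = ph.parse_sdb(path)
        assert len(res.records) == 1
        assert len(res.rejects) == 1
        assert "latitude" in res.rejects.iloc[0]["reject_reason"]

    def test_unknown_species_routed_to_rejects(self, tmp_path):
        path = write_csv(tmp_path, ["A,,10,10,100,5,H. floresiensis,14C,"])
        res = ph.parse_sdb(path)
        assert len(res.records) == 0 and len(res.rejects) == 1

    def test_missing_mandatory_column_raises_with_name(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site_name,lon,lat,species\nA,10,10,sapiens\n")
        with pytest.raises(ValueError, match="age_ka"):
            ph.parse_sdb(path)

    def test_canonicalization_handles_prefixes(self):
        assert canonical_species("Homo sapiens") == "sapiens"
        assert canonical_species("H. ergaster") == "ergaster"
        assert canonical_species("NEANDERTHAL") == "neanderthalensis"


class TestFilter:
    def test_age_window(self):
        recs = [
            make_record(age=25.0),  # too young
            make_record(age=100.0),
            make_record(age=2100.0),  # too old
        ]
        kept = ph.filter_records(recs)
        assert [r.age_ka for r in kept] == [100.0]
        assert AGE_WINDOW_KA == (30.0, 2000.0)

    def test_habilis_ergaster_merge(self):
        recs = [
            make_record(species=("habilis",)),
            make_record(species=("ergaster",)),
            make_record(species=("habilis", "ergaster")),
        ]
        kept = ph.filter_records(recs)
        assert all(r.attributions == ("early_african_homo",) for r in kept)

    def test_region_exclusion_by_column_and_bbox(self):
        recs = [
            make_record(region="Americas", lon=20.0),
            make_record(region="", lon=-70.0, lat=-30.0),  # Americas bbox
            make_record(region="", lon=130.0, lat=-25.0),  # Australia bbox
            make_record(region="Europe", lon=10.0, lat=45.0),
        ]
        kept = ph.filter_records(recs)
        assert len(kept) == 1 and kept[0].region == "Europe"


class TestScenarios:
    def _records(self):
        return [
            make_record(site="S1", layer="L1", age=100.0, dt=10.0),
            make_record(site="S1", layer="L1", age=120.0, dt=5.0),
            make_record(site="S1", layer="L1", age=90.0, dt=5.0),
            make_record(site="S2", layer="", age=200.0, dt=10.0,
                        species=("sapiens", "neanderthalensis")),
            make_record(site="S3", layer="A", age=300.0, dt=10.0,
                        species=("heidelbergensis",)),
        ]

    def test_multiple_tier1_drops_ambiguous_keeps_every_date(self):
        sc = ph.build_scenario(self._records(), ph.ScenarioConfig("multiple", 1))
        assert sc.total == 4  # 3 dated entries of S1/L1 + S3; S2 ambiguous
        assert len(sc.by_species["sapiens"]) == 3

    def test_multiple_tier2_resolves_ambiguous(self):
        sc = ph.build_scenario(self._records(), ph.ScenarioConfig("multiple", 2, seed=1))
        assert sc.total == 5

    def test_single_mode_one_entry_per_layer_with_age_envelope(self):
        sc = ph.build_scenario(self._records(), ph.ScenarioConfig("single", 1))
        sap = sc.by_species["sapiens"]
        assert len(sap) == 1  # S1/L1 collapsed
        rec = sap[0]
        # envelope over [85, 125]: midpoint 105, half-span 20
        assert rec.age_ka == pytest.approx(105.0)
        assert rec.age_uncertainty_ka == pytest.approx(20.0)
        assert sc.total == 2

    def test_tier2_without_seed_is_an_error(self):
        with pytest.raises(ValueError, match="seed"):
            ph.build_scenario(self._records(), ph.ScenarioConfig("multiple", 2))

    def test_tier2_choice_deterministic_and_unbiased(self):
        """A two-way ambiguous record resolves to each candidate about half
        the time over many seeds (binomial concentration, +-0.02)."""
        rec = [make_record(site="X", species=("sapiens", "neanderthalensis"), dt=0.0)]
        first = ph.build_scenario(rec, ph.ScenarioConfig("multiple", 2, seed=77))
        again = ph.build_scenario(rec, ph.ScenarioConfig("multiple", 2, seed=77))
        assert summarize(first) == summarize(again)
        n_sap = 0
        for seed in range(10_000):
            sc = ph.build_scenario(rec, ph.ScenarioConfig("multiple", 2, seed=seed))
            n_sap += len(sc.by_species["sapiens"])
        assert abs(n_sap / 10_000 - 0.5) < 0.02

    def test_scenario_count_orderings_on_synthetic_sdb(self):
        """Tier 2 keeps at least as many entries as tier 1; single-date
        collapses layers so its totals never exceed multiple-date."""
        rng = np.random.default_rng(42)
        recs = []
        for i in range(120):
            multi = rng.uniform() < 0.2
            species = ("sapiens", "heidelbergensis") if multi else ("sapiens",)
            recs.append(
                make_record(
                    site=f"S{i % 30}", layer=f"L{i % 3}",
                    age=float(rng.uniform(35, 1900)), dt=float(rng.uniform(0, 20)),
                    species=species,
                )
            )
        totals = {}
        for mode in ("multiple", "single"):
            for tier in (1, 2):
                cfg = ph.ScenarioConfig(mode, tier, seed=5 if tier == 2 else None)
                totals[(mode, tier)] = ph.build_scenario(recs, cfg).total
        assert totals[("multiple", 2)] >= totals[("multiple", 1)]
        assert totals[("single", 2)] >= totals[("single", 1)]
        assert totals[("single", 1)] <= totals[("multiple", 1)]
        assert totals[("single", 2)] <= totals[("multiple", 2)]


class TestAges:
    def test_zero_uncertainty_degenerate(self, rng):
        r = make_record(age=150.0, dt=0.0)
        assert (ph.sample_ages(r, 5, rng) == 150.0).all()

    def test_uniform_draws_bounded_and_centred(self, rng):
        r = make_record(age=100.0, dt=10.0)
        draws = ph.sample_ages(r, 10_000, rng)
        assert draws.min() >= 90.0 and draws.max() <= 110.0
        assert abs(draws.mean() - 100.0) < 0.5

    def test_truncnorm_mode(self, rng):
        r = make_record(age=100.0, dt=10.0)
        draws = ph.sample_ages(r, 4000, rng, distribution="truncnorm")
        assert draws.min() >= 90.0 and draws.max() <= 110.0
        assert draws.std() < 10.0 / np.sqrt(3)  # tighter than uniform

    def test_single_draw(self, rng):
        r = make_record(age=100.0, dt=3.0)
        assert ph.sample_ages(r, 1, rng).shape == (1,)


def test_summarize_counts_and_fractions():
    recs = [make_record(species=("sapiens",), site=f"s{i}", layer=str(i)) for i in range(6)]
    recs += [make_record(species=("neanderthalensis",), site=f"n{i}", layer=str(i)) for i in range(4)]
    sc = ph.build_scenario(recs, ph.ScenarioConfig("multiple", 1))
    s = summarize(sc)
    assert s["total"] == 10
    assert s["fractions"]["sapiens"] == pytest.approx(0.6)
    assert s["fractions"]["neanderthalensis"] == pytest.approx(0.4)
    empty = ph.build_scenario([], ph.ScenarioConfig("multiple", 1))
    assert summarize(empty)["total"] == 0


def test_roundtrip_records_frame(tmp_path):
    recs = [make_record(), make_record(species=("sapiens", "erectus"), site="B")]
    df = records_to_frame(recs)
    back = ph.species_db.frame_to_records(df)
    assert back == recs
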