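"""Generator contracts: determinism, ground truth, and category mix."""

import numpy as np
import pytest
from scipy import stats as st

from srnamir._seq import revcomp
from srnamir.fold import duplex_stats
from srnamir.preprocess import classify_and_trim
from srnamir.simulate import (
    SimulationConfig,
    plant_hairpin,
    simulate_libraries,
    truth_tsv,
    write_bundle,
)
from conftest import small_config


def test_config_invariants_are_validated():
    with pytest.raises(ValueError):
        SimulationConfig(library_depth=0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(n_star_detectable=11, n_novel_hairpins=10).validate()
    bad = SimulationConfig()
    bad.contaminant_fractions = {"ncrna": 1.2}
    with pytest.raises(ValueError):
        bad.validate()


def test_perfect_complement_construction_pairs_every_base(rng):
    hp = plant_hairpin("GCTAGCATCGGATCCGTAGCA", 0, 6, rng, overhang3=0)
    ds = duplex_stats(hp.fold, hp.mature_start, hp.mature_len, overhang3=0)
    assert ds.overlap_bp == hp.mature_len


def test_star_has_two_nt_three_prime_overhang(rng):
    hp = plant_hairpin("GCTAGCATCGGATCCGTAGCA", 0, 6, rng)
    # pairing region of the star is the revcomp of the mature minus its
    # 3'-terminal 2 nt; the star's own 3' end carries 2 extra bases
    assert hp.star[:hp.mature_len - 2] == revcomp(hp.mature[:-2])
    assert len(hp.star) == hp.mature_len


def test_plant_hairpin_input_validation(rng):
    with pytest.raises(Exception):
        plant_hairpin("GCTAGCATCGGANCCGTAGCA", 0, 6, rng)
    with pytest.raises(ValueError):
        plant_hairpin("GCTAGCATCGGATCCGTAGCA", 5, 6, rng)
    with pytest.raises(ValueError):
        plant_hairpin("GCTAGCATCGGATCCGTAGCA", 0, 2, rng)


def test_same_seed_gives_byte_identical_bundles(tmp_path):
    cfg = small_config(seed=21)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = write_bundle(simulate_libraries(cfg), d1)
    p2 = write_bundle(simulate_libraries(small_config(seed=21)), d2)
    for key in p1:
        assert open(p1[key], "rb").read() == open(p2[key], "rb").read(), key


def test_truth_matures_occur_in_their_precursors(small_bundle):
    refs = small_bundle.references
    for t in small_bundle.truth:
        if t.kind != "novel":
            continue
        precursor = refs[t.ref_id][t.precursor_start:t.precursor_end]
        assert t.sequence in precursor


def test_planted_fc_plan_shapes_expected_counts(small_bundle):
    for t in small_bundle.truth:
        if t.kind == "star":
            continue
        ratio = np.log2(t.expected_BR / t.expected_BS)
        assert ratio == pytest.approx(t.true_fc, abs=1e-9)
        # composition effects keep the realized fc near the planned one
        assert abs(t.true_fc - t.planned_fc) < 0.2


def test_contaminant_free_simulation_is_all_clean():
    cfg = small_config(seed=31)
    cfg.contaminant_fractions = {k: 0.0 for k in cfg.contaminant_fractions}
    cfg.library_depth = 5000
    b = simulate_libraries(cfg)
    _, stats = classify_and_trim(b.reads_BR, cfg.adapter3, cfg.adapter5,
                                 library="BR")
    assert stats.high_quality == stats.raw == stats.clean
    for cat in ("adapter3_null", "insert_null", "adapter5_contaminant",
                "smaller_than_min", "polyA"):
        assert getattr(stats, cat) == 0


def test_category_proportions_match_configuration(small_bundle):
    """Chi-square goodness of fit of removal categories vs configured mix."""
    cfg = small_bundle.config
    _, stats = classify_and_trim(small_bundle.reads_BR, cfg.adapter3,
                                 cfg.adapter5, library="BR")
    fr = cfg.contaminant_fractions
    observed, expected = [], []
    for cat in ("adapter3_null", "insert_null", "adapter5_contaminant",
                "smaller_than_min", "polyA"):
        observed.append(getattr(stats, cat))
        expected.append(fr[cat] * cfg.library_depth)
    observed.append(stats.raw - sum(observed))
    expected.append(cfg.library_depth - sum(expected))
    _, p = st.chisquare(observed, f_exp=expected)
    assert p > 0.01


def test_truth_table_serializes(small_bundle):
    text = truth_tsv(small_bundle.truth)
    assert text.count("\n") == len(small_bundle.truth) + 1
    assert text.startswith("entity_id\t")
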