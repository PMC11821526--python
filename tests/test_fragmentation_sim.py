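"""Fragmentation simulator: event sampling, PSM emission, recovery metrics."""

import numpy as np
import pytest

from ctapkit.ctap_caller import annotate_psms, call_sites
from ctapkit.digest import TerminusClass
from ctapkit.fragmentation_sim import (
    GroundTruth,
    SimConfig,
    evaluate_recovery,
    random_proteins,
    simulate_cleavage_events,
    simulate_psm_table,
)
from ctapkit.masses import AMIDATION_DELTA_DA
from ctapkit.sequence_io import ProteinRecord


def test_no_cleavage_yields_intact_species_only():
    proteins = [ProteinRecord("P1", "", "MKARPGEKAAAA")]
    species, truth = simulate_cleavage_events(
        proteins, SimConfig(p_cleave=0.0), np.random.default_rng(0)
    )
    assert len(truth) == 0
    assert [(s.start, s.end, s.amidated_cterm) for s in species] == [(1, 12, False)]


def test_pam_mode_restricts_to_pre_glycine_bonds():
    proteins = [ProteinRecord("P1", "", "AAGAA")]
    cfg = SimConfig(p_cleave=1.0, pam_mode=True, detectable_only=False)
    _, truth = simulate_cleavage_events(proteins, cfg, np.random.default_rng(0))
    assert {t.position for t in truth.sites} == {2}
    assert truth.sites[0].mechanism == "pam"


def test_certain_cleavage_hits_every_bond():
    proteins = [ProteinRecord("P1", "", "ACDEFGHIKL")]
    cfg = SimConfig(p_cleave=1.0, detectable_only=False)
    species, truth = simulate_cleavage_events(proteins, cfg, np.random.default_rng(0))
    assert {t.position for t in truth.sites} == set(range(1, 10))
    # one intact + two fragments per cleaved bond
    assert len(species) == 1 + 2 * 9


def test_detectable_only_excludes_protease_bonds():
    """With trypsin active, bonds downstream of K/R are confounded with
    enzymatic termini and must never enter the ground truth."""
    rng = np.random.default_rng(5)
    proteins = random_proteins(20, rng, length_range=(100, 200))
    cfg = SimConfig(p_cleave=1.0)
    _, truth = simulate_cleavage_events(proteins, cfg, np.random.default_rng(1))
    by_id = {p.id: p for p in proteins}
    from ctapkit.digest import cleavage_positions

    assert len(truth) > 0
    for site in truth.sites:
        assert site.position not in cleavage_positions(by_id[site.protein_id], "trypsin")


def test_zero_detection_probability_gives_empty_table():
    proteins = random_proteins(5, np.random.default_rng(2))
    cfg = SimConfig(detection_prob=0.0)
    rng = np.random.default_rng(3)
    species, truth = simulate_cleavage_events(proteins, cfg, rng)
    assert simulate_psm_table(species, truth, cfg, rng, proteins=proteins) == []
    assert len(truth) > 0


def test_seeded_determinism():
    proteins = random_proteins(10, np.random.default_rng(7))
    cfg = SimConfig(seed=42)

    def run():
        rng = np.random.default_rng(cfg.seed)
        species, truth = simulate_cleavage_events(proteins, cfg, rng)
        return simulate_psm_table(species, truth, cfg, rng, proteins=proteins), truth

    psms_a, truth_a = run()
    psms_b, truth_b = run()
    assert psms_a == psms_b
    assert truth_a.sites == truth_b.sites


def test_noise_free_truth_sites_all_have_amidated_neo_psms():
    proteins = random_proteins(30, np.random.default_rng(11))
    cfg = SimConfig(false_amidation_rate=0.0, decoy_rate=0.0, detection_prob=1.0)
    rng = np.random.default_rng(13)
    species, truth = simulate_cleavage_events(proteins, cfg, rng)
    psms = simulate_psm_table(species, truth, cfg, rng, proteins=proteins)
    annotated = annotate_psms(psms, proteins, min_probability=0.0)

    amidated_neo_ends = {
        (a.protein_id, a.end)
        for a in annotated
        if a.amidated and a.c_class is TerminusClass.NEO
    }
    assert truth.keys() <= amidated_neo_ends
    # amidation never appears on enzymatic or annotated C termini without noise
    assert not any(a.amidated and a.c_class is not TerminusClass.NEO for a in annotated)


def test_amidated_delta_matches_constant():
    proteins = random_proteins(10, np.random.default_rng(21))
    cfg = SimConfig(false_amidation_rate=0.0, decoy_rate=0.0, detection_prob=1.0)
    rng = np.random.default_rng(22)
    species, truth = simulate_cleavage_events(proteins, cfg, rng)
    psms = simulate_psm_table(species, truth, cfg, rng, proteins=proteins)
    deltas = {p.cterm_delta_da for p in psms}
    assert deltas <= {0.0, AMIDATION_DELTA_DA}


def test_evaluate_recovery_conventions():
    truth = GroundTruth(sites=[])
    assert evaluate_recovery([], truth) == {"precision": 1.0, "recall": 1.0, "f1": 1.0}
    r = evaluate_recovery([("P", i) for i in range(1, 11)], {("P", i) for i in range(1, 10)})
    assert r["precision"] == pytest.approx(0.9)
    assert r["recall"] == pytest.approx(1.0)
    r = evaluate_recovery([], {("P", 1)})
    assert r["recall"] == 0.0 and r["precision"] == 1.0


def test_oxidative_bias_preset():
    bias = SimConfig.oxidative_bias()
    assert bias["C"] > 1.0 and bias["K"] > 1.0


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(p_cleave=1.5)
    with pytest.raises(ValueError):
        SimConfig(psm_count_lambda=-1)
    with pytest.raises(ValueError):
        SimConfig(min_peptide_len=10, max_peptide_len=5)


def test_residue_bias_recovered_by_flanking_enrichment(sim_proteins):
    """Cleavage biased toward Cys/Lys upstream residues shows up as positive
    log2 enrichment at the amidated-residue position.  Glu-C digestion is
    used so that Lys-adjacent bonds are not confounded with protease sites."""
    from ctapkit.motif_stats import flanking_enrichment

    cfg = SimConfig(
        p_cleave=0.02,
        residue_bias=SimConfig.oxidative_bias(),
        protease="glu-c",
        false_amidation_rate=0.0,
        decoy_rate=0.0,
        detection_prob=1.0,
    )
    rng = np.random.default_rng(31)
    species, truth = simulate_cleavage_events(sim_proteins, cfg, rng)
    psms = simulate_psm_table(species, truth, cfg, rng, proteins=sim_proteins)
    annotated = annotate_psms(psms, sim_proteins, rule="glu-c", min_probability=0.0)
    sites = call_sites(annotated)
    assert len(sites) > 100
    matrix = flanking_enrichment(sites, sim_proteins, window=3)
    enr = matrix.enrichment
    assert enr.loc["C", -1] > 0.5
    assert enr.loc["K", -1] > 0.5
    # the two biased residues are the strongest cells at the site position
    assert set(enr[-1].sort_values(ascending=False).index[:2]) == {"C", "K"}
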