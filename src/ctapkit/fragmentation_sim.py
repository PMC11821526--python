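"""Ground-truthed simulator of α-amidating backbone cleavage.

Models the two mechanisms that leave a C-terminal primary amide on the
upstream fragment: diffuse hydroxyl-radical attack (any backbone bond, with
an optional per-residue bias) and PAM-style processing (cleavage of a
C-terminal glycine, i.e. only bonds whose downstream residue is Gly).  Each
sampled bond yields an amidated N-terminal fragment, an unmodified
complementary fragment, and a GroundTruth entry; intact copies of every
protein remain in the species pool.  The species are then digested in
silico and emitted as a noisy PSM table whose coordinates refer to the
parent protein, so neo-termini stay detectable downstream.

Noise model: with probability ε an unmodified PSM's C-terminal delta is set
to the amidation value (false amidation); with probability δ any PSM's delta
is overwritten by a random decoy ladder shift (k ≠ −1); peptides are
detected with probability d, each detected peptide producing 1 + Poisson(λ)
PSMs with Beta(8,1) confidence scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ctapkit.digest import PeptideSpan, cleavage_positions, digest_full, get_rule
from ctapkit.masses import AMIDATION_DELTA_DA, DEFAULT_LADDER, ShiftLadder
from ctapkit.sequence_io import ProteinRecord, PsmRow

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the fragmentation simulator.

    ``detectable_only`` restricts ground-truth sites to bonds whose cleavage
    is observable in principle: the bond must not coincide with a protease
    site (amidation there is confounded with enzymatic termini by
    definition) and its zero-missed-cleavage evidence peptide must fall in
    the search length window and map uniquely in the database.
    """

    p_cleave: float = 0.01
    residue_bias: Mapping[str, float] = field(default_factory=dict)
    pam_mode: bool = False
    false_amidation_rate: float = 0.01
    decoy_rate: float = 0.01
    detection_prob: float = 0.8
    psm_count_lambda: float = 5.0
    protease: str = "trypsin"
    max_missed: int = 1
    min_peptide_len: int = 7
    max_peptide_len: int = 50
    detectable_only: bool = True
    sample_id: str = "sim1"
    seed: int = 0

    def __post_init__(self):
        for name in ("p_cleave", "false_amidation_rate", "decoy_rate", "detection_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.psm_count_lambda < 0:
            raise ValueError("psm_count_lambda must be >= 0")
        if self.min_peptide_len < 1 or self.max_peptide_len < self.min_peptide_len:
            raise ValueError("bad peptide length window")

    @staticmethod
    def oxidative_bias() -> dict:
        """Residue-bias preset raising cleavage upstream of Cys and Lys."""
        return {"C": 3.0, "K": 2.0}


@dataclass(frozen=True)
class TruthSite:
    protein_id: str
    position: int  # 1-based residue carrying the amide
    mechanism: str  # "radical" | "pam"

    @property
    def key(self) -> tuple:
        return (self.protein_id, self.position)


@dataclass
class GroundTruth:
    """True amidation sites with their generating mechanism."""

    sites: list

    def keys(self) -> set:
        return {s.key for s in self.sites}

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class FragmentSpecies:
    """A protein species in the sample: intact protein or cleavage fragment,
    in parent-protein coordinates."""

    protein_id: str
    start: int
    end: int
    amidated_cterm: bool = False


def random_proteins(
    n: int,
    rng: np.random.Generator,
    length_range: tuple = (100, 400),
    id_prefix: str = "SIM",
) -> list[ProteinRecord]:
    """Uniform-composition random proteins for simulation studies."""
    lo, hi = length_range
    out = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(AA20[j] for j in rng.integers(0, len(AA20), size=L))
        out.append(ProteinRecord(id=f"{id_prefix}{i:04d}", description="synthetic", sequence=seq))
    return out


def _rng_for(config: SimConfig, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def _detectable(seq: str, i: int, cut_set: set, db: str, config: SimConfig) -> bool:
    if i in cut_set:
        return False  # confounded with an enzymatic terminus
    last_cut = max((c for c in cut_set if c < i), default=0)
    pep = seq[last_cut:i]
    if not (config.min_peptide_len <= len(pep) <= config.max_peptide_len):
        return False
    return db.count(pep) == 1


def simulate_cleavage_events(
    proteins: Sequence[ProteinRecord],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
):
    """Sample α-amidating cleavage events; return (species, GroundTruth).

    Each bond i|i+1 cleaves independently with probability
    ``p_cleave · residue_bias[upstream residue]`` (clamped to 1); in
    ``pam_mode`` only bonds whose downstream residue is Gly are eligible.
    Fragments are generated independently per bond from the intact template;
    intact copies of all proteins are always retained.
    """
    rng = _rng_for(config, rng)
    rule = get_rule(config.protease)
    db = "|".join(p.sequence for p in proteins)

    species: list[FragmentSpecies] = []
    truth_sites: list[TruthSite] = []
    mechanism = "pam" if config.pam_mode else "radical"
    for protein in proteins:
        seq = protein.sequence
        L = protein.length
        species.append(FragmentSpecies(protein.id, 1, L, amidated_cterm=False))
        cut_set = set(cleavage_positions(protein, rule))
        for i in range(1, L):
            if config.pam_mode and seq[i] != "G":
                continue
            p = min(1.0, config.p_cleave * config.residue_bias.get(seq[i - 1], 1.0))
            if rng.random() >= p:
                continue
            if config.detectable_only and not _detectable(seq, i, cut_set, db, config):
                continue
            species.append(FragmentSpecies(protein.id, 1, i, amidated_cterm=True))
            species.append(FragmentSpecies(protein.id, i + 1, L, amidated_cterm=False))
            truth_sites.append(TruthSite(protein.id, i, mechanism))
    return species, GroundTruth(sites=truth_sites)


def simulate_psm_table(
    species: Sequence[FragmentSpecies],
    truth: GroundTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    proteins: Optional[Sequence[ProteinRecord]] = None,
    ladder: ShiftLadder = DEFAULT_LADDER,
) -> list[PsmRow]:
    """Digest every species and emit a noisy PSM table (parent coordinates).

    ``proteins`` must cover every parent id referenced by the species (it is
    required; passing the same list used for simulate_cleavage_events).
    """
    if proteins is None:
        raise ValueError("proteins (the parent database) must be supplied")
    rng = _rng_for(config, rng)
    rule = get_rule(config.protease)
    by_id = {p.id: p for p in proteins}
    decoy_ks = sorted(k for k in ladder.k_values if k != -1)

    rows: list[PsmRow] = []
    for sp in species:
        parent = by_id[sp.protein_id]
        frag_seq = parent.sequence[sp.start - 1 : sp.end]
        frag_len = len(frag_seq)
        for span in digest_full(frag_seq, rule, config.max_missed):
            if not (config.min_peptide_len <= span.length <= config.max_peptide_len):
                continue
            ps = sp.start + span.start - 1
            pe = sp.start + span.end - 1
            base_delta = (
                AMIDATION_DELTA_DA
                if (sp.amidated_cterm and span.end == frag_len)
                else 0.0
            )
            if rng.random() >= config.detection_prob:
                continue
            n_psms = 1 + int(rng.poisson(config.psm_count_lambda))
            for _ in range(n_psms):
                delta = base_delta
                if delta == 0.0 and rng.random() < config.false_amidation_rate:
                    delta = AMIDATION_DELTA_DA
                if rng.random() < config.decoy_rate:
                    delta = decoy_ks[int(rng.integers(0, len(decoy_ks)))] * ladder.step_da
                rows.append(
                    PsmRow(
                        sample_id=config.sample_id,
                        peptide=parent.sequence[ps - 1 : pe],
                        protein_id=parent.id,
                        start=ps,
                        end=pe,
                        prev_aa=parent.sequence[ps - 2] if ps > 1 else "-",
                        next_aa=parent.sequence[pe] if pe < parent.length else "-",
                        cterm_delta_da=delta,
                        probability=float(rng.beta(8.0, 1.0)),
                        charge=int(rng.integers(2, 4)),
                    )
                )
    return rows


def evaluate_recovery(called_sites, truth) -> dict:
    """Site-level precision/recall/F1 of called sites against ground truth.

    Both empty: precision = recall = 1 by convention.  Empty calls against
    non-empty truth: recall 0, precision reported as 1.0 (no false calls).
    """
    called = {s.key if hasattr(s, "key") else (s[0], s[1]) for s in called_sites}
    true = truth.keys() if hasattr(truth, "keys") and not isinstance(truth, set) else set(truth)
    tp = len(called & true)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(true) if true else 1.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return {"precision": precision, "recall": recall, "f1": f1}
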