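"""Core CTAP analysis: PSM annotation, amidated-site calling, category
cross-tabulation, the decoy-shift noise control, and site-set overlap.

A CTAP cleavage site is a (protein, position) pair where the residue at
``position`` carries a C-terminal amide (−0.984016 Da) on at least one PSM
whose C terminus is a *neo* terminus — i.e. explained neither by the
annotated protein C terminus nor by the protease.  Amidation observed at
enzymatic or annotated termini cannot be distinguished from chemical
artifacts and never supports a site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from ctapkit.digest import (
    EnzymaticStatus,
    TerminusClass,
    classify_peptide_termini,
    get_rule,
)
from ctapkit.masses import DEFAULT_LADDER, ShiftLadder
from ctapkit.sequence_io import ProteinRecord, PsmRow

logger = logging.getLogger(__name__)

#: Default PSM confidence filter.  Deliberately stricter than permissive
#: engine-level pre-filtering; tune per dataset via ``min_probability``.
DEFAULT_MIN_PROBABILITY = 0.9

C_CLASSES = (TerminusClass.ANNOTATED_C, TerminusClass.ENZYMATIC, TerminusClass.NEO)


@dataclass
class AnnotatedPsm:
    """A PsmRow plus terminus classes, enzymatic status and amidation call."""

    psm: PsmRow
    n_class: TerminusClass
    c_class: TerminusClass
    status: EnzymaticStatus
    amidated: bool
    shift_bin: Optional[int]
    ambiguous: bool = False  # peptide maps to >1 database protein

    # passthroughs used throughout downstream code
    @property
    def protein_id(self) -> str:
        return self.psm.protein_id

    @property
    def peptide(self) -> str:
        return self.psm.peptide

    @property
    def start(self) -> int:
        return self.psm.start

    @property
    def end(self) -> int:
        return self.psm.end

    @property
    def sample_id(self) -> str:
        return self.psm.sample_id

    @property
    def probability(self) -> float:
        return self.psm.probability


@dataclass(frozen=True)
class CtapSite:
    """A called α-amidating cleavage site: the amidated residue's 1-based
    position, with aggregated PSM evidence."""

    protein_id: str
    position: int
    residue: str
    n_psms: int
    n_distinct_peptides: int
    samples: frozenset
    max_probability: float

    @property
    def key(self) -> tuple:
        return (self.protein_id, self.position)


@dataclass
class CategoryTable:
    """Cross-tab of C-terminus class × amidation, in both conditional
    directions: fraction amidated per class, and class share among amidated."""

    n_total: dict
    n_amidated: dict

    classes = tuple(c.value for c in C_CLASSES)

    def __post_init__(self):
        for cls in self.classes:
            self.n_total.setdefault(cls, 0)
            self.n_amidated.setdefault(cls, 0)

    @property
    def fraction_amidated(self) -> dict:
        return {
            cls: (self.n_amidated[cls] / self.n_total[cls]) if self.n_total[cls] else 0.0
            for cls in self.classes
        }

    @property
    def share_among_amidated(self) -> dict:
        total = sum(self.n_amidated.values())
        return {
            cls: (self.n_amidated[cls] / total) if total else 0.0 for cls in self.classes
        }


@dataclass
class NoiseReport:
    """Neo-C-terminus PSM counts per ladder bin.

    ``signal_ratio`` divides the k = −1 (amidation) count by the mean count
    over the decoy bins, zeros included; infinite when all decoys are empty
    but signal is present, 0.0 when everything is empty.
    """

    counts: dict

    @property
    def signal_ratio(self) -> float:
        signal = self.counts.get(-1, 0)
        decoys = [n for k, n in self.counts.items() if k != -1]
        mean_decoy = sum(decoys) / len(decoys) if decoys else 0.0
        if mean_decoy == 0.0:
            return math.inf if signal > 0 else 0.0
        return signal / mean_decoy


@dataclass(frozen=True)
class OverlapReport:
    n_a: int
    n_b: int
    shared: int
    jaccard: float


def _ambiguity_index(proteins: Sequence[ProteinRecord]):
    """Concatenated database for substring-multiplicity checks; '|' separates
    entries so peptides cannot straddle records."""
    return "|".join(p.sequence for p in proteins)


def annotate_psms(
    psms: Iterable[PsmRow],
    proteins: Sequence[ProteinRecord],
    rule="trypsin",
    ladder: ShiftLadder = DEFAULT_LADDER,
    min_probability: float = DEFAULT_MIN_PROBABILITY,
    exclude_ambiguous: bool = True,
    strict: bool = False,
    dropped: Optional[list] = None,
) -> list[AnnotatedPsm]:
    """Validate and annotate PSMs against the protein database.

    Rows failing the probability filter or whose peptide does not match the
    protein substring at the claimed coordinates are dropped with a logged
    reason (collected into ``dropped`` when given; raised when ``strict``).
    Terminus classes come from the protease rule; the amidation flag is the
    k = −1 ladder-bin assignment of the C-terminal delta.

    When ``exclude_ambiguous`` is set, peptides occurring more than once in
    the database are annotated ``ambiguous`` and ignored by site calling.
    """
    rule = get_rule(rule)
    by_id = {p.id: p for p in proteins}
    db = _ambiguity_index(proteins) if exclude_ambiguous else None
    ambiguity_cache: dict[str, bool] = {}

    out: list[AnnotatedPsm] = []
    for psm in psms:
        reason = None
        protein = by_id.get(psm.protein_id)
        if protein is None:
            reason = f"unknown protein {psm.protein_id!r}"
        elif psm.end > protein.length:
            reason = "span outside protein"
        elif protein.sequence[psm.start - 1 : psm.end] != psm.peptide:
            reason = "sequence mismatch"
        elif psm.probability < min_probability:
            reason = "below probability threshold"
        if reason is not None:
            if strict:
                raise ValueError(f"PSM {psm.peptide!r}: {reason}")
            logger.debug("dropping PSM %r: %s", psm.peptide, reason)
            if dropped is not None:
                dropped.append((psm, reason))
            continue

        n_class, c_class, status = classify_peptide_termini(protein, psm.start, psm.end, rule)
        shift_bin = ladder.assign(psm.cterm_delta_da) if psm.cterm_delta_da != 0.0 else None
        ambiguous = False
        if exclude_ambiguous:
            if psm.peptide not in ambiguity_cache:
                ambiguity_cache[psm.peptide] = db.count(psm.peptide) > 1
            ambiguous = ambiguity_cache[psm.peptide]
        out.append(
            AnnotatedPsm(
                psm=psm,
                n_class=n_class,
                c_class=c_class,
                status=status,
                amidated=shift_bin == -1,
                shift_bin=shift_bin,
                ambiguous=ambiguous,
            )
        )
    return out


def call_sites(annotated: Iterable[AnnotatedPsm], require_neo: bool = True) -> list[CtapSite]:
    """Group amidated neo-C-terminus PSMs by (protein, end position) into
    CtapSite objects, ordered by (protein_id, position)."""
    groups: dict[tuple, list[AnnotatedPsm]] = {}
    for apsm in annotated:
        if not apsm.amidated or apsm.ambiguous:
            continue
        if require_neo and apsm.c_class is not TerminusClass.NEO:
            continue
        groups.setdefault((apsm.protein_id, apsm.end), []).append(apsm)

    sites = []
    for (pid, pos), members in sorted(groups.items()):
        sites.append(
            CtapSite(
                protein_id=pid,
                position=pos,
                residue=members[0].peptide[-1],
                n_psms=len(members),
                n_distinct_peptides=len({m.peptide for m in members}),
                samples=frozenset(m.sample_id for m in members),
                max_probability=max(m.probability for m in members),
            )
        )
    return sites


def category_stats(annotated: Iterable[AnnotatedPsm]) -> CategoryTable:
    """Cross-tabulate C-terminus class against the amidation flag."""
    n_total = {cls.value: 0 for cls in C_CLASSES}
    n_amidated = {cls.value: 0 for cls in C_CLASSES}
    for apsm in annotated:
        n_total[apsm.c_class.value] += 1
        if apsm.amidated:
            n_amidated[apsm.c_class.value] += 1
    return CategoryTable(n_total=n_total, n_amidated=n_amidated)


def shift_noise_control(
    annotated: Iterable[AnnotatedPsm], ladder: ShiftLadder = DEFAULT_LADDER
) -> NoiseReport:
    """Count neo-C-terminus PSMs per ladder bin; the amidation bin (k = −1)
    is the signal, all other multiples of 0.984 Da are technical decoys."""
    counts = {k: 0 for k in sorted(ladder.k_values)}
    for apsm in annotated:
        if apsm.c_class is TerminusClass.NEO and apsm.shift_bin is not None:
            counts[apsm.shift_bin] += 1
    return NoiseReport(counts=counts)


def _site_keys(sites) -> set:
    out = set()
    for s in sites:
        out.add(s.key if isinstance(s, CtapSite) else (s[0], s[1]))
    return out


def overlap_sites(sites_a, sites_b) -> OverlapReport:
    """Exact overlap of two site sets keyed by (protein_id, position)."""
    a, b = _site_keys(sites_a), _site_keys(sites_b)
    shared = len(a & b)
    union = len(a) + len(b) - shared
    jaccard = (shared / union) if union else 1.0  # two empty sets are identical
    return OverlapReport(n_a=len(a), n_b=len(b), shared=shared, jaccard=jaccard)
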