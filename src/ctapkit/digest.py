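"""In-silico protease model and peptide-terminus classification.

Conventions
-----------
Coordinates are 1-based inclusive.  A cleavage *bond index* ``i`` means the
backbone bond between residues ``i`` and ``i+1``; a peptide spanning
``[start, end]`` therefore has N-terminal bond ``start - 1`` and C-terminal
bond ``end``.

A peptide terminus is *enzymatic* when it coincides with a protease cleavage
bond, or with an annotated protein terminus — allowing for clipping of the
initiator methionine at the N terminus (start == 2 with Met at residue 1).
A terminus explained by neither is a *neo* terminus; a peptide with exactly
one neo terminus is semi-enzymatic, with two it is non-enzymatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Union

from ctapkit.sequence_io import ProteinRecord, STANDARD_AA


class TerminusClass(str, Enum):
    ANNOTATED_N = "ANNOTATED_N"
    MET_CLIPPED_N = "MET_CLIPPED_N"
    ENZYMATIC = "ENZYMATIC"
    ANNOTATED_C = "ANNOTATED_C"
    NEO = "NEO"


class EnzymaticStatus(str, Enum):
    FULL = "FULL"
    SEMI = "SEMI"
    NONE = "NONE"


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: cut on ``side`` of any residue in ``residues``,
    vetoed when the residue adjacent on the cut side is in ``blocked_next``."""

    name: str
    residues: frozenset
    side: str  # "C" or "N"
    blocked_next: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "residues", frozenset(self.residues))
        object.__setattr__(self, "blocked_next", frozenset(self.blocked_next))
        if not self.residues:
            raise ValueError(f"rule {self.name!r}: empty residue set")
        if not self.residues <= STANDARD_AA:
            raise ValueError(f"rule {self.name!r}: residues outside the 20 standard amino acids")
        if self.side not in ("C", "N"):
            raise ValueError(f"rule {self.name!r}: side must be 'C' or 'N', got {self.side!r}")


#: Built-in rules.  Trypsin/ArgC/chymotrypsin block cleavage before proline;
#: "stricttrypsin" is the no-proline-block variant; trypsin-N cuts on the
#: N-terminal side of K/R; Glu-C cuts after D/E.
BUILTIN_RULES: dict[str, ProteaseRule] = {
    "trypsin": ProteaseRule("trypsin", frozenset("KR"), "C", frozenset("P")),
    "stricttrypsin": ProteaseRule("stricttrypsin", frozenset("KR"), "C"),
    "glu-c": ProteaseRule("glu-c", frozenset("DE"), "C"),
    "argc": ProteaseRule("argc", frozenset("R"), "C", frozenset("P")),
    "trypsin-n": ProteaseRule("trypsin-n", frozenset("KR"), "N"),
    "chymotrypsin": ProteaseRule("chymotrypsin", frozenset("FWYL"), "C", frozenset("P")),
}


def get_rule(name_or_rule: Union[str, ProteaseRule]) -> ProteaseRule:
    if isinstance(name_or_rule, ProteaseRule):
        return name_or_rule
    try:
        return BUILTIN_RULES[name_or_rule.lower()]
    except KeyError:
        raise KeyError(
            f"unknown protease {name_or_rule!r}; built-ins: {sorted(BUILTIN_RULES)}"
        ) from None


@dataclass(frozen=True)
class PeptideSpan:
    protein_id: str
    start: int
    end: int
    n_missed: int = 0

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad span [{self.start},{self.end}]")
        if self.n_missed < 0:
            raise ValueError("n_missed must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _sequence_of(protein) -> str:
    return protein.sequence if isinstance(protein, ProteinRecord) else str(protein)


def _id_of(protein) -> str:
    return protein.id if isinstance(protein, ProteinRecord) else ""


@lru_cache(maxsize=4096)
def _cleavage_positions_cached(sequence: str, rule: ProteaseRule) -> tuple:
    L = len(sequence)
    out = []
    for i in range(1, L):  # bond between residues i and i+1 (1-based)
        if rule.side == "C":
            if sequence[i - 1] in rule.residues and sequence[i] not in rule.blocked_next:
                out.append(i)
        else:
            if sequence[i] in rule.residues and sequence[i - 1] not in rule.blocked_next:
                out.append(i)
    return tuple(out)


def cleavage_positions(protein, rule) -> list[int]:
    """Sorted bond indices ``i`` (cut between residues ``i`` and ``i+1``)."""
    return list(_cleavage_positions_cached(_sequence_of(protein), get_rule(rule)))


def digest_full(protein, rule, max_missed: int = 1) -> list[PeptideSpan]:
    """Fully enzymatic peptides: substrings delimited by consecutive cleavage
    bonds (plus the protein termini), merged across at most ``max_missed``
    internal sites."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = _sequence_of(protein)
    pid = _id_of(protein)
    bounds = [0, *_cleavage_positions_cached(seq, get_rule(rule)), len(seq)]
    spans = []
    for j in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            if j + 1 + m >= len(bounds):
                break
            spans.append(PeptideSpan(pid, bounds[j] + 1, bounds[j + 1 + m], n_missed=m))
    return spans


def classify_peptide_termini(protein, start: int, end: int, rule):
    """Classify both termini of the span and derive its enzymatic status.

    N terminus: ANNOTATED_N at start==1; MET_CLIPPED_N at start==2 when the
    protein begins with Met; ENZYMATIC when bond ``start-1`` is a cleavage
    site; NEO otherwise.  C terminus: ANNOTATED_C at end==length; ENZYMATIC
    when bond ``end`` is a cleavage site; NEO otherwise.  Status is FULL with
    no neo terminus, SEMI with one, NONE with two.
    """
    seq = _sequence_of(protein)
    L = len(seq)
    if not (1 <= start <= end <= L):
        raise ValueError(f"span [{start},{end}] outside protein of length {L}")
    cuts = set(_cleavage_positions_cached(seq, get_rule(rule)))

    if start == 1:
        n_class = TerminusClass.ANNOTATED_N
    elif start == 2 and seq[0] == "M":
        n_class = TerminusClass.MET_CLIPPED_N
    elif (start - 1) in cuts:
        n_class = TerminusClass.ENZYMATIC
    else:
        n_class = TerminusClass.NEO

    if end == L:
        c_class = TerminusClass.ANNOTATED_C
    elif end in cuts:
        c_class = TerminusClass.ENZYMATIC
    else:
        c_class = TerminusClass.NEO

    n_neo = (n_class is TerminusClass.NEO) + (c_class is TerminusClass.NEO)
    status = (EnzymaticStatus.FULL, EnzymaticStatus.SEMI, EnzymaticStatus.NONE)[n_neo]
    return n_class, c_class, status


def enumerate_semi(
    protein,
    rule,
    max_missed: int = 1,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[PeptideSpan]:
    """All spans with at least one enzymatic terminus (FULL or SEMI status),
    length within bounds and at most ``max_missed`` internal cleavage sites.

    Superset of :func:`digest_full` filtered by length.  O(L^2) in protein
    length — intended for search-space construction at modest scale.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = _sequence_of(protein)
    pid = _id_of(protein)
    L = len(seq)
    if max_len is None:
        max_len = L
    if max_len < min_len:
        raise ValueError(f"max_len {max_len} < min_len {min_len}")
    rule = get_rule(rule)
    cuts = _cleavage_positions_cached(seq, rule)
    cut_set = set(cuts)
    # prefix[i] = number of cleavage bonds <= i
    prefix = [0] * (L + 1)
    n = 0
    for i in range(1, L + 1):
        if i in cut_set:
            n += 1
        prefix[i] = n

    met_start = seq[0] == "M"
    out = []
    for start in range(1, L + 1):
        n_enz = start == 1 or (start == 2 and met_start) or (start - 1) in cut_set
        for end in range(start + min_len - 1, min(L, start + max_len - 1) + 1):
            c_enz = end == L or end in cut_set
            if not (n_enz or c_enz):
                continue
            missed = prefix[end - 1] - prefix[start - 1] if end > start else 0
            if missed > max_missed:
                continue
            out.append(PeptideSpan(pid, start, end, n_missed=missed))
    return out
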