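"""Pooled isokinetic peptide-library interaction-screen quantification.

The library randomizes the three C-terminal positions over the 19 natural
amino acids excluding cysteine (19^3 = 6,859 members per chemistry, amide or
acid).  Reporter-ion quantification follows the pooled-IP convention: per
peptide, reporter intensities are summed across multiple detections, then
every per-peptide channel sum is scaled by the total input-channel sum over
all library peptides, yielding relative intensities comparable across runs.
Enrichment is the IP/input ratio of those relative intensities.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

LIBRARY_ALPHABET = "ADEFGHIKLMNPQRSTVWY"  # 19 aa, no Cys


@dataclass(frozen=True)
class LibraryDesign:
    """Isokinetic library: ``n_variable`` randomized C-terminal positions on
    a fixed scaffold, synthesized as C-terminal amide or free acid."""

    alphabet: str = LIBRARY_ALPHABET
    n_variable: int = 3
    scaffold: str = ""
    chemistry: str = "amide"

    def __post_init__(self):
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet has repeated residues")
        if "C" in self.alphabet:
            raise ValueError("cysteine is excluded from the library alphabet")
        if self.chemistry not in ("amide", "acid"):
            raise ValueError("chemistry must be 'amide' or 'acid'")
        if self.n_variable < 1:
            raise ValueError("n_variable must be >= 1")


def enumerate_library(design: LibraryDesign = LibraryDesign()) -> list[str]:
    """All alphabet^n_variable members appended to the scaffold, in
    lexicographic order of the variable positions."""
    alphabet = sorted(design.alphabet)
    return [
        design.scaffold + "".join(combo)
        for combo in itertools.product(alphabet, repeat=design.n_variable)
    ]


def collapse_indistinguishable(
    sequences: Iterable[str],
    equivalences: Optional[Mapping[str, str]] = None,
) -> dict[str, list]:
    """Collapse sequences indistinguishable by MS into classes.

    ``equivalences`` maps residues to a class representative (default
    {'L': 'I'}, the isobaric Leu/Ile pair).  Returns {class image:
    member list}, insertion-ordered by first occurrence.
    """
    if equivalences is None:
        equivalences = {"L": "I"}
    table = str.maketrans(dict(equivalences))
    classes: dict[str, list] = {}
    for seq in sequences:
        classes.setdefault(seq.translate(table), []).append(seq)
    return classes


@dataclass
class PeptideQuant:
    """Relative reporter intensities and IP/input enrichment for one library
    peptide.  Enrichment is undefined (None) when the peptide was absent
    from the input channel."""

    peptide: str
    chemistry: str
    rel_input: float
    rel_ip: float

    def __post_init__(self):
        if self.rel_input < 0 or self.rel_ip < 0:
            raise ValueError("relative intensities must be >= 0")

    @property
    def enrichment(self) -> Optional[float]:
        if self.rel_input == 0:
            return None
        return self.rel_ip / self.rel_input

    @property
    def log2_enrichment(self) -> Optional[float]:
        e = self.enrichment
        if e is None:
            return None
        return math.log2(e) if e > 0 else -math.inf


def quantify_relative_intensities(
    psm_rows,
    input_channel: str,
    ip_channel: str,
    library: Iterable[str],
    chemistry: str = "amide",
) -> list[PeptideQuant]:
    """Sum reporter intensities per peptide and channel, scale by the total
    input-channel sum over all library peptides.

    PSMs whose peptide is not a library member are logged and dropped.
    Raises when the total input intensity is zero.
    """
    library = list(library)
    lib_set = set(library)
    in_sum: dict[str, float] = {}
    ip_sum: dict[str, float] = {}
    for row in psm_rows:
        peptide = row.peptide if hasattr(row, "peptide") else row["peptide"]
        reporter = row.reporter if hasattr(row, "reporter") else row["reporter"]
        if peptide not in lib_set:
            logger.debug("dropping non-library peptide %r", peptide)
            continue
        if not reporter:
            continue
        in_sum[peptide] = in_sum.get(peptide, 0.0) + float(reporter.get(input_channel, 0.0))
        ip_sum[peptide] = ip_sum.get(peptide, 0.0) + float(reporter.get(ip_channel, 0.0))

    total_input = sum(in_sum.values())
    if total_input <= 0:
        raise ValueError("total input-channel intensity is zero")
    return [
        PeptideQuant(
            peptide=pep,
            chemistry=chemistry,
            rel_input=in_sum.get(pep, 0.0) / total_input,
            rel_ip=ip_sum.get(pep, 0.0) / total_input,
        )
        for pep in sorted(set(in_sum) | set(ip_sum))
    ]


@dataclass
class ChemistryComparison:
    n_bound_amide: int
    n_bound_acid: int
    binder_threshold: float
    fold_enrichment: float
    position_preferences: pd.DataFrame  # aa rows x variable-position columns


def compare_chemistries(
    quant_amide: Sequence[PeptideQuant],
    quant_acid: Sequence[PeptideQuant],
    binder_threshold: float = 1.0,
    n_variable: int = 3,
) -> ChemistryComparison:
    """Compare amide- and acid-chemistry screens of the same library.

    A binder has defined enrichment >= ``binder_threshold``.  Fold
    enrichment is the ratio of median defined enrichments (amide / acid).
    Position preferences count residues at the ``n_variable`` C-terminal
    positions of bound amide peptides.
    """
    amide_defined = [q.enrichment for q in quant_amide if q.enrichment is not None]
    acid_defined = [q.enrichment for q in quant_acid if q.enrichment is not None]
    if not amide_defined or not acid_defined:
        raise ValueError("need defined enrichments in both chemistries")

    amide_binders = [q for q in quant_amide if q.enrichment is not None and q.enrichment >= binder_threshold]
    acid_binders = [q for q in quant_acid if q.enrichment is not None and q.enrichment >= binder_threshold]

    med_acid = median(acid_defined)
    fold = median(amide_defined) / med_acid if med_acid > 0 else math.inf

    positions = list(range(-n_variable, 0))
    aas = sorted(set("".join(q.peptide[-n_variable:] for q in amide_binders))) or ["-"]
    prefs = pd.DataFrame(0, index=aas, columns=positions)
    for q in amide_binders:
        tail = q.peptide[-n_variable:]
        for rel, aa in zip(positions, tail):
            prefs.loc[aa, rel] += 1

    return ChemistryComparison(
        n_bound_amide=len(amide_binders),
        n_bound_acid=len(acid_binders),
        binder_threshold=binder_threshold,
        fold_enrichment=fold,
        position_preferences=prefs,
    )
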