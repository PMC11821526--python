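"""Sequence statistics around cleavage sites and at protein C termini.

Two related questions are answered here.  First, whether α-amidating
cleavage prefers particular flanking residues: counts of amino acids at
positions −w..+w around called sites versus the database background, as a
pseudocounted log2 enrichment matrix.  Second, the C-terminal degron motif
read by the FBXO31 D334N neosubstrate receptor: a basic residue (Lys/Arg)
at position −3 and a hydrophobic residue Φ at the very terminus (−1),
i.e. [Lys/Arg]-X-Φ-COOH.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ctapkit.sequence_io import ProteinRecord

AA20 = sorted("ACDEFGHIKLMNPQRSTVWY")

#: Hydrophobic set Φ for the terminal position.  Ala is included (Tyr→Ala
#: retains degradation in the mutational series); Thr is excluded (Tyr→Thr
#: abolishes it).
DEFAULT_PHI = frozenset("AFILMVWY")
DEFAULT_BASIC = frozenset("KR")


@dataclass(frozen=True)
class CTermMotif:
    """C-terminal degron motif: basic at −3, hydrophobic (Φ) at −1, counted
    from the C terminus with −1 = terminal residue."""

    basic: frozenset = DEFAULT_BASIC
    phi: frozenset = DEFAULT_PHI

    def __post_init__(self):
        if not self.basic or not self.phi:
            raise ValueError("motif residue sets must be non-empty")


def motif_match(c_terminal_sequence: str, motif: CTermMotif = CTermMotif()) -> bool:
    """True iff the sequence ends in [basic]-X-[Φ]: position −3 in the basic
    set and position −1 (the terminal residue) in Φ."""
    if len(c_terminal_sequence) < 3:
        raise ValueError("sequence must be at least 3 residues long")
    return c_terminal_sequence[-3] in motif.basic and c_terminal_sequence[-1] in motif.phi


@dataclass
class FlankMatrix:
    """Counts and log2 enrichment of residues flanking cleavage sites.

    Positions −w..−1 are upstream (−1 = the amidated residue itself), +1..+w
    downstream.  ``counts`` and ``enrichment`` are DataFrames with amino-acid
    rows and position columns; ``background`` maps residue → frequency.
    """

    window: int
    counts: pd.DataFrame
    background: pd.Series
    pseudocount: float
    n_sites: int

    @property
    def positions(self) -> list[int]:
        return list(self.counts.columns)

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts / totals.replace(0, np.nan)

    @property
    def enrichment(self) -> pd.DataFrame:
        """log2((f_obs + α')/(f_bg + α')) per cell, where α' is the
        pseudocount expressed as a frequency, α/(n_position + 20α).

        Adding the same α' to both raw frequencies keeps every cell finite,
        makes identical distributions come out exactly 0, and leaves the
        matrix invariant under duplicating the background."""
        a = self.pseudocount
        totals = self.counts.sum(axis=0).astype(float)
        alpha_freq = a / (totals + 20 * a)  # per-position frequency pseudocount
        f_obs = self.counts.div(totals.replace(0, np.nan), axis=1).fillna(0.0)
        f_bg = (self.background * 1.0).reindex(AA20).fillna(0.0)
        num = f_obs.add(alpha_freq, axis=1)
        den = pd.DataFrame(
            np.add.outer(f_bg.to_numpy(), alpha_freq.to_numpy()),
            index=AA20,
            columns=self.counts.columns,
        )
        return np.log2(num / den)


def _background_frequencies(proteins: Sequence[ProteinRecord]) -> pd.Series:
    counts = Counter()
    for p in proteins:
        counts.update(ch for ch in p.sequence if ch in set(AA20))
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no standard residues in background proteins")
    return pd.Series({aa: counts.get(aa, 0) / total for aa in AA20})


def flanking_enrichment(
    sites,
    proteins: Sequence[ProteinRecord],
    window: int = 5,
    pseudocount: float = 1.0,
) -> FlankMatrix:
    """Residue counts at positions −window..+window around each site versus
    the residue composition of the supplied database.

    A site contributes to a position only when the window fully covers it
    (sites near protein termini are partially counted).  Position −1 is the
    amidated residue; positive positions are downstream of the cleaved bond.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("empty site list")
    by_id = {p.id: p for p in proteins}
    positions = [p for p in range(-window, window + 1) if p != 0]
    tally = Counter()
    for site in sites:
        key = site.key if hasattr(site, "key") else (site[0], site[1])
        protein = by_id[key[0]]
        pos = key[1]  # 1-based; residue at pos is position -1
        for rel in positions:
            # residue index (1-based) at relative position rel
            idx = pos + rel + 1 if rel < 0 else pos + rel
            if 1 <= idx <= protein.length:
                tally[(protein.sequence[idx - 1], rel)] += 1
    counts = pd.DataFrame(0, index=AA20, columns=positions)
    for (aa, rel), n in tally.items():
        if aa in counts.index:
            counts.loc[aa, rel] = n
    return FlankMatrix(
        window=window,
        counts=counts,
        background=_background_frequencies(proteins),
        pseudocount=pseudocount,
        n_sites=len(sites),
    )


def cterm_position_enrichment(
    sequences: Iterable[str],
    background_sequences: Iterable[str],
    k: int = 5,
    pseudocount: float = 1.0,
):
    """Position-anchored residue enrichment over the last ``k`` residues.

    Counts residues at positions −k..−1 from the C terminus of ``sequences``
    and of ``background_sequences``, then forms the same pseudocounted log2
    ratio as :class:`FlankMatrix`.  Returns (frequency DataFrame, enrichment
    DataFrame), rows = amino acids, columns = positions −k..−1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sequences = list(sequences)
    background_sequences = list(background_sequences)
    if not sequences or not background_sequences:
        raise ValueError("empty sequence set")
    for group in (sequences, background_sequences):
        short = [s for s in group if len(s) < k]
        if short:
            raise ValueError(f"{len(short)} sequence(s) shorter than k={k}")

    positions = list(range(-k, 0))

    def count(group):
        frame = pd.DataFrame(0, index=AA20, columns=positions)
        for s in group:
            for rel in positions:
                aa = s[rel]
                if aa in frame.index:
                    frame.loc[aa, rel] += 1
        return frame

    obs, bg = count(sequences), count(background_sequences)
    a = pseudocount
    alpha_freq = a / (obs.sum(axis=0).astype(float) + 20 * a)
    f_obs = obs / obs.sum(axis=0)
    f_bg = bg / bg.sum(axis=0)
    # fixed frequency pseudocount on both sides: exact 0 for identical
    # distributions, invariant under background duplication
    enrichment = np.log2(f_obs.add(alpha_freq, axis=1) / f_bg.add(alpha_freq, axis=1))
    freq = obs / obs.sum(axis=0).replace(0, np.nan)
    return freq, enrichment
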