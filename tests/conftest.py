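"""Shared fixtures and independent brute-force oracles.

The digestion oracles below re-apply the textual rule definitions by
exhaustive substring enumeration; they deliberately share no code with
ctapkit.digest so that agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctapkit.sequence_io import ProteinRecord


# ---------------------------------------------------------------------------
# brute-force digestion oracles


def brute_force_cuts(seq: str, residues, side, blocked) -> set:
    """Scan every bond i (between residues i and i+1, 1-based)."""
    cuts = set()
    for i in range(1, len(seq)):
        before, after = seq[i - 1], seq[i]
        if side == "C" and before in residues and after not in blocked:
            cuts.add(i)
        if side == "N" and after in residues and before not in blocked:
            cuts.add(i)
    return cuts


def brute_force_terminus_enzymatic(seq: str, start: int, end: int, cuts: set):
    """(n_terminus_explained, c_terminus_explained) per the textual rules:
    annotated termini, Met clipping at start==2, or a protease cleavage bond."""
    n_ok = start == 1 or (start == 2 and seq[0] == "M") or (start - 1) in cuts
    c_ok = end == len(seq) or end in cuts
    return n_ok, c_ok


def brute_force_full_digest(seq: str, rule, max_missed: int) -> set:
    """All substrings with both termini on cleavage bonds / protein termini
    (Met clipping excluded: full peptides are delimited by consecutive cut
    bonds, so the N terminus must be a bond or the annotated start) and at
    most max_missed internal cleavage bonds."""
    cuts = brute_force_cuts(seq, rule.residues, rule.side, rule.blocked_next)
    out = set()
    for start in range(1, len(seq) + 1):
        for end in range(start, len(seq) + 1):
            n_ok = start == 1 or (start - 1) in cuts
            c_ok = end == len(seq) or end in cuts
            missed = sum(1 for c in cuts if start <= c <= end - 1)
            if n_ok and c_ok and missed <= max_missed:
                out.add((start, end, missed))
    return out


def brute_force_semi_digest(seq: str, rule, max_missed: int, min_len: int, max_len: int) -> set:
    """All substrings with at least one explained terminus (including
    Met-clipped N), length in bounds, internal cleavage bonds <= max_missed."""
    cuts = brute_force_cuts(seq, rule.residues, rule.side, rule.blocked_next)
    out = set()
    for start in range(1, len(seq) + 1):
        for end in range(start, len(seq) + 1):
            if not (min_len <= end - start + 1 <= max_len):
                continue
            n_ok, c_ok = brute_force_terminus_enzymatic(seq, start, end, cuts)
            missed = sum(1 for c in cuts if start <= c <= end - 1)
            if (n_ok or c_ok) and missed <= max_missed:
                out.add((start, end, missed))
    return out


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def toy_protein() -> ProteinRecord:
    return ProteinRecord(id="P1", description="toy", sequence="MKARPGEK")


@pytest.fixture(scope="session")
def sim_proteins():
    """The simulation database used across recovery tests: 200 random
    proteins of length 100-400, fixed seed."""
    from ctapkit.fragmentation_sim import random_proteins

    return random_proteins(200, np.random.default_rng(1234))


@pytest.fixture(scope="session")
def oracle_proteins():
    """Short random proteins (length 20-60) for brute-force digestion checks."""
    rng = np.random.default_rng(99)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for i in range(200):
        L = int(rng.integers(20, 61))
        out.append(
            ProteinRecord(
                id=f"O{i:03d}",
                description="oracle",
                sequence="".join(aa[j] for j in rng.integers(0, 20, size=L)),
            )
        )
    return out
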