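"""Monoisotopic mass arithmetic and the C-terminal mass-shift ladder.

Amidation of a peptide C terminus replaces the terminal -OH with -NH2, a net
elemental change of +N +H −O = −0.984016 Da.  Because deamidation-like and
isotope-error artifacts cluster at multiples of ~0.984 Da, site calling is
validated against a decoy ladder of shifts k·0.984 Da for k = ±1..±3, where
the k = −1 bin is the amidation signal and all other bins measure technical
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from pyteomics import mass as _pmass

WATER_MONO = _pmass.calculate_mass(formula="H2O")

#: Canonical amidation delta (Da): mass(N) + mass(H) - mass(O).
AMIDATION_DELTA_DA = -0.984016

_AMBIGUOUS = set("XBZU")


@dataclass(frozen=True)
class ModDelta:
    """A named modification mass delta, optionally tied to an elemental
    composition it must reproduce.

    Registered deltas are conventionally quoted rounded to 4–6 decimals
    (e.g. oxidation as 15.9949), so the construction-time consistency check
    allows 5e-5 Da (half a unit in the fourth decimal) against the exact
    composition mass.
    """

    name: str
    delta_da: float
    composition: Optional[dict] = None

    def __post_init__(self):
        if self.composition is not None:
            computed = _pmass.calculate_mass(
                composition=_pmass.Composition(dict(self.composition))
            )
            if abs(computed - self.delta_da) > 5e-5:
                raise ValueError(
                    f"mod {self.name!r}: delta {self.delta_da} Da does not match "
                    f"composition mass {computed:.6f} Da"
                )

    def composition_mass(self) -> float:
        if self.composition is None:
            raise ValueError(f"mod {self.name!r} has no composition")
        return _pmass.calculate_mass(composition=_pmass.Composition(dict(self.composition)))


#: Registry of the modifications used throughout: variable peptide C-terminal
#: amidation, Met oxidation, protein C-terminal acetylation, and fixed Cys
#: carbamidomethylation.  Each delta is validated against its elemental
#: composition at import time.
MOD_REGISTRY: dict[str, ModDelta] = {
    "amidation": ModDelta("amidation", AMIDATION_DELTA_DA, {"N": 1, "H": 1, "O": -1}),
    "oxidation": ModDelta("oxidation", 15.99490, {"O": 1}),
    "acetylation_protein_cterm": ModDelta(
        "acetylation_protein_cterm", 42.01060, {"C": 2, "H": 2, "O": 1}
    ),
    "carbamidomethyl": ModDelta("carbamidomethyl", 57.021464, {"C": 2, "H": 3, "N": 1, "O": 1}),
}


def modification_delta(name: str) -> ModDelta:
    """Look up a registered modification delta by name."""
    try:
        return MOD_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown modification {name!r}; registry: {sorted(MOD_REGISTRY)}"
        ) from None


def register_modification(name: str, delta_da: float, composition: Optional[dict] = None) -> ModDelta:
    """Extend the registry (e.g. from a config file)."""
    mod = ModDelta(name, delta_da, composition)
    MOD_REGISTRY[name] = mod
    return mod


def peptide_monoisotopic_mass(sequence: str, mods: Iterable[Union[ModDelta, float, str]] = ()) -> float:
    """Monoisotopic peptide mass: residue masses + water + modification deltas.

    ``mods`` may mix ModDelta objects, registry names and raw deltas in Da.
    Ambiguous residues (X/B/Z/U) raise; callers must exclude such peptides.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence) & _AMBIGUOUS
    if bad:
        raise ValueError(f"ambiguous residue(s) {sorted(bad)} in {sequence!r}")
    try:
        total = sum(_pmass.std_aa_mass[aa] for aa in sequence) + WATER_MONO
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc} in {sequence!r}") from None
    for mod in mods:
        if isinstance(mod, str):
            mod = modification_delta(mod)
        total += mod.delta_da if isinstance(mod, ModDelta) else float(mod)
    return total


@dataclass(frozen=True)
class ShiftLadder:
    """Decoy ladder of C-terminal mass shifts: multiples k·step for
    k in ``k_values`` (0 excluded), spanning −2.952…+2.952 Da by default.

    The k = −1 bin center is pinned to the exact amidation delta
    (−0.984016 Da); decoy centers sit at k·0.984 as printed for the control.
    """

    step_da: float = 0.984
    k_values: frozenset = frozenset({-3, -2, -1, 1, 2, 3})
    tolerance_da: float = 0.005
    signal_center_da: float = AMIDATION_DELTA_DA

    def __post_init__(self):
        object.__setattr__(self, "k_values", frozenset(self.k_values))
        if 0 in self.k_values:
            raise ValueError("k = 0 (no shift) cannot be a ladder bin")
        if not self.k_values:
            raise ValueError("empty ladder")
        if not 0 < self.tolerance_da < self.step_da / 2:
            raise ValueError("tolerance must be positive and < step/2 (bins must not overlap)")

    def center(self, k: int) -> float:
        """Bin center in Da (exact amidation delta at k = −1)."""
        if k not in self.k_values:
            raise KeyError(f"k={k} not in ladder")
        return self.signal_center_da if k == -1 else k * self.step_da

    def shifts(self) -> list[float]:
        """Nominal shift values k·step, sorted (the printed control ladder)."""
        return sorted(k * self.step_da for k in self.k_values)

    def assign(self, observed_delta_da: float) -> Optional[int]:
        best_k, best_err = None, None
        for k in self.k_values:
            err = abs(observed_delta_da - self.center(k))
            if best_err is None or err < best_err:
                best_k, best_err = k, err
        return best_k if best_err is not None and best_err <= self.tolerance_da else None


DEFAULT_LADDER = ShiftLadder()


def assign_cterm_shift_bin(observed_delta_da: float, ladder: ShiftLadder = DEFAULT_LADDER) -> Optional[int]:
    """Map an observed C-terminal delta to its ladder bin k, or None when it
    falls between bins.  k = −1 flags amidation."""
    return ladder.assign(observed_delta_da)
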