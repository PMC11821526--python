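"""Readers/writers for the formats the pipeline touches.

FASTA protein databases come in through Biopython; PSM tables are
tab-separated text in the FragPipe dialect (1-based inclusive coordinates,
``-`` as the terminus sentinel for flanking residues).  All result tables
(sites, category stats, noise reports, library quantities, binding fits) are
written as deterministic TSV with a fixed column order and can be read back
into the same objects.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
TOLERATED_AA = set("XUBZ")
TERMINUS_SENTINEL = "-"

PSM_REQUIRED_COLUMNS = (
    "sample_id",
    "peptide",
    "protein_id",
    "start",
    "end",
    "cterm_delta_da",
    "probability",
)


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry; the coordinate frame for all peptides and sites."""

    id: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_AA - TOLERATED_AA
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_nonstandard(self) -> bool:
        """True when the sequence contains X/U/B/Z placeholders."""
        return bool(set(self.sequence) & TOLERATED_AA)


@dataclass
class PsmRow:
    """One peptide identification with its C-terminal mass delta.

    Coordinates are 1-based inclusive against the mapped protein.  ``prev_aa``
    / ``next_aa`` carry the flanking residue or '-' at a protein terminus.
    ``other_mods`` lists (position-in-peptide, delta Da) pairs for
    modifications other than the C-terminal delta.  ``extras`` preserves any
    foreign columns untouched.
    """

    sample_id: str
    peptide: str
    protein_id: str
    start: int
    end: int
    prev_aa: str = TERMINUS_SENTINEL
    next_aa: str = TERMINUS_SENTINEL
    cterm_delta_da: float = 0.0
    other_mods: list = field(default_factory=list)
    probability: float = 1.0
    charge: Optional[int] = None
    reporter: Optional[dict] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"PSM {self.peptide!r}: bad coordinates start={self.start} end={self.end}"
            )
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError(
                f"PSM {self.peptide!r}: span [{self.start},{self.end}] does not "
                f"match peptide length {len(self.peptide)}"
            )
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"PSM {self.peptide!r}: probability {self.probability} outside [0,1]")


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a FASTA protein database into ProteinRecord objects.

    The header token before the first whitespace becomes the id; sequences
    are uppercased.  Empty files, duplicate ids and illegal residues raise.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if entry.id in seen:
            raise ValueError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, description=entry.description, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _parse_other_mods(text) -> list:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return []
    mods = []
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        pos, delta = item.split(":")
        mods.append((int(pos), float(delta)))
    return mods


def _format_other_mods(mods) -> str:
    return ";".join(f"{int(p)}:{float(d)!r}" for p, d in mods)


def read_psm_table(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    strict: bool = False,
    with_report: bool = False,
):
    """Read a tab-separated PSM table into PsmRow objects.

    ``column_map`` translates foreign header names to the canonical ones
    (sample_id, peptide, protein_id, start, end, prev_aa, next_aa,
    cterm_delta_da, other_mods, probability, charge, reporter_<channel>...).
    Rows violating the PsmRow invariants checkable without the FASTA are
    dropped with a logged reason (or raise immediately when ``strict``).
    With ``with_report`` the return value is ``(rows, rejected)`` where
    rejected is a list of (row_number, reason).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in PSM_REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"PSM table {path}: missing required column(s) {missing}")

    known = set(PSM_REQUIRED_COLUMNS) | {"prev_aa", "next_aa", "other_mods", "charge"}
    reporter_cols = [c for c in frame.columns if c.startswith("reporter_")]
    extra_cols = [c for c in frame.columns if c not in known and c not in reporter_cols]

    rows: list[PsmRow] = []
    rejected: list[tuple[int, str]] = []
    for idx, rec in enumerate(frame.to_dict("records")):
        try:
            reporter = None
            if reporter_cols:
                reporter = {
                    c[len("reporter_"):]: float(rec[c]) for c in reporter_cols if rec[c] != ""
                }
            charge = rec.get("charge", "")
            row = PsmRow(
                sample_id=rec["sample_id"],
                peptide=rec["peptide"],
                protein_id=rec["protein_id"],
                start=int(rec["start"]),
                end=int(rec["end"]),
                prev_aa=rec.get("prev_aa", TERMINUS_SENTINEL) or TERMINUS_SENTINEL,
                next_aa=rec.get("next_aa", TERMINUS_SENTINEL) or TERMINUS_SENTINEL,
                cterm_delta_da=float(rec["cterm_delta_da"]),
                other_mods=_parse_other_mods(rec.get("other_mods")),
                probability=float(rec["probability"]),
                charge=int(charge) if charge not in ("", None) else None,
                reporter=reporter,
                extras={c: rec[c] for c in extra_cols},
            )
        except (ValueError, KeyError) as exc:
            if strict:
                raise ValueError(f"PSM table {path} row {idx + 2}: {exc}") from exc
            logger.warning("dropping PSM row %d: %s", idx + 2, exc)
            rejected.append((idx, str(exc)))
            continue
        rows.append(row)
    if with_report:
        return rows, rejected
    return rows


def write_psm_table(rows: Sequence[PsmRow], path) -> None:
    """Write PsmRow objects as a canonical TSV (inverse of read_psm_table)."""
    channels = sorted({ch for r in rows if r.reporter for ch in r.reporter})
    records = []
    for r in rows:
        rec = {
            "sample_id": r.sample_id,
            "peptide": r.peptide,
            "protein_id": r.protein_id,
            "start": r.start,
            "end": r.end,
            "prev_aa": r.prev_aa,
            "next_aa": r.next_aa,
            "cterm_delta_da": repr(r.cterm_delta_da),
            "other_mods": _format_other_mods(r.other_mods),
            "probability": repr(r.probability),
            "charge": "" if r.charge is None else r.charge,
        }
        for ch in channels:
            rec[f"reporter_{ch}"] = "" if not r.reporter or ch not in r.reporter else repr(r.reporter[ch])
        rec.update(r.extras)
        records.append(rec)
    cols = list(PSM_REQUIRED_COLUMNS[:5]) + ["prev_aa", "next_aa"] + [
        "cterm_delta_da", "other_mods", "probability", "charge",
    ] + [f"reporter_{ch}" for ch in channels]
    extra = [c for c in (records[0] if records else {}) if c not in cols]
    pd.DataFrame.from_records(records, columns=cols + extra).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic result-table output: one fixed schema per kind, exact round-trip.

_SITE_COLUMNS = [
    "protein_id", "position", "residue", "n_psms", "n_distinct_peptides",
    "samples", "max_probability",
]
_CATEGORY_COLUMNS = [
    "c_class", "n_total", "n_amidated", "fraction_amidated", "share_among_amidated",
]
_NOISE_COLUMNS = ["k", "n_psms"]
_QUANT_COLUMNS = [
    "peptide", "chemistry", "rel_input", "rel_ip", "enrichment", "log2_enrichment",
]
_FIT_COLUMNS = ["name", "model", "kd", "rss", "converged", "tight_binding_warning"]

WRITE_KINDS = ("sites", "category_stats", "noise_report", "quant", "fits")


def _sites_to_frame(sites):
    return pd.DataFrame.from_records(
        [
            {
                "protein_id": s.protein_id,
                "position": s.position,
                "residue": s.residue,
                "n_psms": s.n_psms,
                "n_distinct_peptides": s.n_distinct_peptides,
                "samples": ";".join(sorted(s.samples)),
                "max_probability": repr(s.max_probability),
            }
            for s in sites
        ],
        columns=_SITE_COLUMNS,
    )


def _frame_to_sites(frame):
    from ctapkit.ctap_caller import CtapSite

    return [
        CtapSite(
            protein_id=r["protein_id"],
            position=int(r["position"]),
            residue=r["residue"],
            n_psms=int(r["n_psms"]),
            n_distinct_peptides=int(r["n_distinct_peptides"]),
            samples=frozenset(str(r["samples"]).split(";")) if r["samples"] else frozenset(),
            max_probability=float(r["max_probability"]),
        )
        for r in frame.to_dict("records")
    ]


def _category_to_frame(table):
    return pd.DataFrame.from_records(
        [
            {
                "c_class": cls,
                "n_total": table.n_total[cls],
                "n_amidated": table.n_amidated[cls],
                "fraction_amidated": repr(table.fraction_amidated[cls]),
                "share_among_amidated": repr(table.share_among_amidated[cls]),
            }
            for cls in table.classes
        ],
        columns=_CATEGORY_COLUMNS,
    )


def _frame_to_category(frame):
    from ctapkit.ctap_caller import CategoryTable

    recs = frame.to_dict("records")
    return CategoryTable(
        n_total={r["c_class"]: int(r["n_total"]) for r in recs},
        n_amidated={r["c_class"]: int(r["n_amidated"]) for r in recs},
    )


def _noise_to_frame(report):
    return pd.DataFrame.from_records(
        [{"k": k, "n_psms": report.counts[k]} for k in sorted(report.counts)],
        columns=_NOISE_COLUMNS,
    )


def _frame_to_noise(frame):
    from ctapkit.ctap_caller import NoiseReport

    return NoiseReport(counts={int(r["k"]): int(r["n_psms"]) for r in frame.to_dict("records")})


def _quant_to_frame(quants):
    return pd.DataFrame.from_records(
        [
            {
                "peptide": q.peptide,
                "chemistry": q.chemistry,
                "rel_input": repr(q.rel_input),
                "rel_ip": repr(q.rel_ip),
                "enrichment": "" if q.enrichment is None else repr(q.enrichment),
                "log2_enrichment": "" if q.log2_enrichment is None else repr(q.log2_enrichment),
            }
            for q in quants
        ],
        columns=_QUANT_COLUMNS,
    )


def _frame_to_quant(frame):
    from ctapkit.library_screen import PeptideQuant

    out = []
    for r in frame.to_dict("records"):
        out.append(
            PeptideQuant(
                peptide=r["peptide"],
                chemistry=r["chemistry"],
                rel_input=float(r["rel_input"]),
                rel_ip=float(r["rel_ip"]),
            )
        )
    return out


def _fits_to_frame(fits):
    return pd.DataFrame.from_records(
        [
            {
                "name": f.name,
                "model": f.model,
                "kd": repr(f.kd),
                "rss": repr(f.rss),
                "converged": f.converged,
                "tight_binding_warning": f.tight_binding_warning,
            }
            for f in fits
        ],
        columns=_FIT_COLUMNS,
    )


def _frame_to_fits(frame):
    from ctapkit.binding_fit import BindingFitResult

    return [
        BindingFitResult(
            name=r["name"],
            model=r["model"],
            kd=float(r["kd"]),
            rss=float(r["rss"]),
            converged=ast.literal_eval(str(r["converged"])),
            tight_binding_warning=ast.literal_eval(str(r["tight_binding_warning"])),
        )
        for r in frame.to_dict("records")
    ]


_WRITERS = {
    "sites": _sites_to_frame,
    "category_stats": _category_to_frame,
    "noise_report": _noise_to_frame,
    "quant": _quant_to_frame,
    "fits": _fits_to_frame,
}
_READERS = {
    "sites": _frame_to_sites,
    "category_stats": _frame_to_category,
    "noise_report": _frame_to_noise,
    "quant": _frame_to_quant,
    "fits": _frame_to_fits,
}


def write_outputs(objects, kind: str, path) -> None:
    """Write a result-object list as deterministic TSV with a fixed schema.

    ``kind`` is one of sites / category_stats / noise_report / quant / fits.
    Floats are rendered at full precision so that :func:`read_outputs`
    round-trips exactly.
    """
    if kind not in _WRITERS:
        raise ValueError(f"unknown output kind {kind!r}; expected one of {WRITE_KINDS}")
    frame = _WRITERS[kind](objects)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def read_outputs(kind: str, path):
    """Inverse of :func:`write_outputs`."""
    if kind not in _READERS:
        raise ValueError(f"unknown output kind {kind!r}; expected one of {WRITE_KINDS}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return _READERS[kind](frame)
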