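"""Reference-anchored catalytic-residue diagnosis for GH-family proteins.

Diagnostic active-site positions are defined on a structural reference
(for GH45: Tyr8, the catalytic base Asp10, Ala74, the stabilizing Asp114
and the catalytic acid Asp121, numbered on the fungal reference protein).
Each query is anchored to the reference — either through a fresh global
pairwise alignment or through an existing MSA containing the reference
row — and the query letters found at the reference positions are pushed
through an ordered rule table that predicts substrate class:

* loss of either carboxylate of the catalytic dyad -> inactive;
* D->E at the catalytic acid or at the stabilizer -> xyloglucanase
  (the substrate shift from amorphous cellulose to xyloglucan);
* other loss of the stabilizer, or Ala->Gly at the conserved alanine
  -> inactive (low confidence);
* otherwise -> glucanase; Tyr8 substitutions are recorded as warnings
  only (Y->F is known to be tolerated).

The scheme (reference + positions + rules) is a data file so that other
hydrolase families can be diagnosed by supplying a new scheme.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .seqmodel import (GAP, Alignment, SequenceRecord, SequenceError,
                       global_align)

LABELS = ("glucanase", "xyloglucanase", "inactive", "indeterminate")


class SchemeError(ValueError):
    """Raised for a mis-specified reference scheme."""


@dataclass(frozen=True)
class Rule:
    name: str
    position: str
    op: str           # 'is' | 'in' | 'not_in'
    letters: tuple[str, ...]
    label: str | None = None
    confidence: str | None = None

    def matches(self, residues: Mapping[str, str]) -> bool:
        r = residues[self.position]
        if self.op == "is":
            return r == self.letters[0]
        if self.op == "in":
            return r in self.letters
        return r not in self.letters


@dataclass
class ReferenceScheme:
    """Reference sequence + named diagnostic positions + rule table."""

    reference: SequenceRecord
    positions: dict[str, int]          # name -> 1-based ungapped position
    expected: dict[str, str]           # name -> residue in the reference
    rules: list[Rule]
    default_label: str = "glucanase"
    default_confidence: str = "high"
    warnings: list[Rule] = field(default_factory=list)

    def __post_init__(self):
        ref = self.reference.ungapped
        for name, pos in self.positions.items():
            if not 1 <= pos <= len(ref):
                raise SchemeError(
                    f"position {name}={pos} beyond reference length {len(ref)}"
                )
            exp = self.expected.get(name)
            if exp and ref[pos - 1] != exp:
                raise SchemeError(
                    f"reference residue at {name} (position {pos}) is "
                    f"{ref[pos - 1]!r}, scheme expects {exp!r}"
                )

    @property
    def position_names(self) -> list[str]:
        return list(self.positions)


@dataclass(frozen=True)
class DiagnosticProfile:
    """Residue states at the diagnostic positions plus the predicted label."""

    query_id: str
    residues: Mapping[str, str]        # position name -> letter or '-'
    label: str
    confidence: str
    evidence: tuple[str, ...] = ()


def load_scheme(path: str | Path) -> ReferenceScheme:
    """Load a scheme YAML (reference, positions, rules, default, warnings)."""
    doc = yaml.safe_load(Path(path).read_text())
    ref_doc = doc["reference"]
    reference = SequenceRecord(
        id=ref_doc["id"],
        residues="".join(str(ref_doc["residues"]).split()),
        taxon=ref_doc.get("taxon", ""),
    )
    positions, expected = {}, {}
    for name, entry in doc["positions"].items():
        positions[name] = int(entry["position"])
        if "expected" in entry:
            expected[name] = str(entry["expected"])

    def _parse_rules(entries, need_label):
        rules = []
        for entry in entries or []:
            when = entry["when"]
            if len(when) != 1:
                raise SchemeError(
                    f"rule {entry.get('name')!r} must test exactly one position"
                )
            (pos_name, cond), = when.items()
            if pos_name not in positions:
                raise SchemeError(
                    f"rule {entry.get('name')!r} references unknown "
                    f"position {pos_name!r}"
                )
            (op, val), = cond.items()
            if op not in ("is", "in", "not_in"):
                raise SchemeError(f"unknown rule operator {op!r}")
            letters = (str(val),) if op == "is" else tuple(str(v) for v in val)
            rules.append(Rule(
                name=str(entry["name"]), position=pos_name, op=op,
                letters=letters,
                label=entry.get("label") if need_label else None,
                confidence=entry.get("confidence") if need_label else None,
            ))
        return rules

    rules = _parse_rules(doc.get("rules"), need_label=True)
    for r in rules:
        if r.label not in LABELS:
            raise SchemeError(f"rule {r.name!r} has unknown label {r.label!r}")
    default = doc.get("default", {})
    return ReferenceScheme(
        reference=reference,
        positions=positions,
        expected=expected,
        rules=rules,
        default_label=default.get("label", "glucanase"),
        default_confidence=default.get("confidence", "high"),
        warnings=_parse_rules(doc.get("warnings"), need_label=False),
    )


def default_scheme() -> ReferenceScheme:
    """The bundled GH45 scheme (synthetic stand-in reference sequence)."""
    res = importlib.resources.files("gh45tools.data") / "gh45_scheme_synthetic.yaml"
    with importlib.resources.as_file(res) as p:
        return load_scheme(p)


# ---------------------------------------------------------------------------
# Position mapping
# ---------------------------------------------------------------------------

def _reference_columns(scheme: ReferenceScheme, gapped_ref: str) -> dict[str, int]:
    """Alignment column (0-based) of each named reference position."""
    cols: dict[str, int] = {}
    wanted = {pos: name for name, pos in scheme.positions.items()}
    res_no = 0
    for col, ch in enumerate(gapped_ref):
        if ch != GAP:
            res_no += 1
            if res_no in wanted:
                cols[wanted[res_no]] = col
    missing = set(scheme.positions) - set(cols)
    if missing:
        raise SchemeError(
            f"reference row too short for positions {sorted(missing)}"
        )
    return cols


def map_reference_positions(query: SequenceRecord, scheme: ReferenceScheme,
                            mode: str = "pairwise",
                            msa: Alignment | None = None) -> dict[str, str]:
    """Report the query letter at each named reference position.

    ``pairwise`` mode aligns query and reference globally; ``from_msa`` mode
    locates the columns through the reference row of a supplied alignment
    (which must also contain the query row).  A gapped query column yields
    '-'.
    """
    if mode == "pairwise":
        aln = global_align(query.residues.replace(GAP, ""),
                           scheme.reference.ungapped)
        gapped_query, gapped_ref = aln.aligned_a, aln.aligned_b
    elif mode == "from_msa":
        if msa is None:
            raise ValueError("from_msa mode requires an alignment")
        try:
            gapped_ref = msa.row(scheme.reference.id).residues
        except KeyError:
            raise SchemeError(
                f"reference row {scheme.reference.id!r} not present in MSA"
            ) from None
        gapped_query = msa.row(query.id).residues
    else:
        raise ValueError(f"unknown mapping mode {mode!r}")

    cols = _reference_columns(scheme, gapped_ref)
    return {name: gapped_query[col] for name, col in cols.items()}


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_function(query_id: str, residues: Mapping[str, str],
                      scheme: ReferenceScheme) -> DiagnosticProfile:
    """Apply the ordered rule table; the first matching rule wins."""
    missing = set(scheme.positions) - set(residues)
    if missing:
        raise ValueError(f"missing residues for positions {sorted(missing)}")
    for name, r in residues.items():
        if r != GAP and (len(r) != 1 or not r.isalpha()):
            raise ValueError(
                f"invalid residue {r!r} at diagnostic position {name!r} "
                f"of {query_id!r}"
            )
    if any(r == GAP for r in residues.values()):
        gapped = sorted(n for n, r in residues.items() if r == GAP)
        return DiagnosticProfile(
            query_id, dict(residues), "indeterminate", "low",
            tuple(f"gap_at_{n}" for n in gapped),
        )
    for rule in scheme.rules:
        if rule.matches(residues):
            return DiagnosticProfile(
                query_id, dict(residues), rule.label, rule.confidence,
                (rule.name,),
            )
    evidence = tuple(
        f"warning:{w.name}" for w in scheme.warnings if w.matches(residues)
    )
    return DiagnosticProfile(
        query_id, dict(residues), scheme.default_label,
        scheme.default_confidence, evidence,
    )


def diagnose(queries: Sequence[SequenceRecord], scheme: ReferenceScheme,
             msa: Alignment | None = None) -> list[DiagnosticProfile]:
    """Map positions and classify every query (MSA mode when one is given)."""
    mode = "from_msa" if msa is not None else "pairwise"
    return [
        classify_function(
            q.id, map_reference_positions(q, scheme, mode=mode, msa=msa), scheme
        )
        for q in queries
    ]


def profiles_to_frame(profiles: Iterable[DiagnosticProfile],
                      scheme: ReferenceScheme) -> pd.DataFrame:
    """Diagnosis matrix: one row per query, residue columns, label, evidence."""
    names = scheme.position_names
    rows = []
    for p in profiles:
        row = {"id": p.query_id}
        row.update({n: p.residues[n] for n in names})
        row["label"] = p.label
        row["confidence"] = p.confidence
        row["evidence"] = ";".join(p.evidence)
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", *names, "label", "confidence",
                                       "evidence"])
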