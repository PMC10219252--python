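"""File I/O: JSON Lines records and gold annotations, entity files,
score CSVs and evaluation reports.

JSON Lines is the record interchange format: one JSON object per line, one
line per patient. Column order in the scores CSV is fixed (patient_id, the
catalog features in catalog order, risk_factor, true_label) so runs diff
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Iterable, Iterator

import pandas as pd

from .phenotype import PatientRecord
from .pipeline import NoteEntity
from .extract import ExtractedEntity
from .synthetic import GoldAnnotation, GoldMention

__all__ = [
    "read_records",
    "write_records",
    "write_gold",
    "read_gold",
    "write_entities",
    "read_entities",
    "write_scores_csv",
    "read_scores_csv",
    "write_report",
]


def read_records(path) -> Iterator[PatientRecord]:
    """Stream patient records from a JSON Lines file."""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield PatientRecord.from_dict(json.loads(line))


def write_records(records: Iterable[PatientRecord], path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")
            n += 1
    return n


def write_gold(golds: Iterable[GoldAnnotation], path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for g in golds:
            d = {
                "patient_id": g.patient_id,
                "mentions": [dataclasses.asdict(m) for m in g.mentions],
                "true_features": sorted(g.true_features),
                "vetoed_features": sorted(g.vetoed_features),
                "intended_risk_factor": g.intended_risk_factor,
                "true_label": g.true_label,
            }
            fh.write(json.dumps(d, sort_keys=True) + "\n")
            n += 1
    return n


def read_gold(path) -> Iterator[GoldAnnotation]:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            yield GoldAnnotation(
                patient_id=d["patient_id"],
                mentions=tuple(
                    GoldMention(
                        term_id=m["term_id"],
                        note_index=m["note_index"],
                        sentence_index=m["sentence_index"],
                        token_span=tuple(m["token_span"]),
                        polarity=m["polarity"],
                    )
                    for m in d["mentions"]
                ),
                true_features=frozenset(d["true_features"]),
                vetoed_features=frozenset(d.get("vetoed_features", [])),
                intended_risk_factor=d["intended_risk_factor"],
                true_label=d["true_label"],
            )


def write_entities(per_patient: Iterable[tuple[str, list[NoteEntity]]], path) -> int:
    """Write per-patient entity lists as JSON Lines."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for patient_id, note_entities in per_patient:
            d = {
                "patient_id": patient_id,
                "entities": [
                    {
                        "note_index": ne.note_index,
                        "sentence_index": ne.entity.sentence_index,
                        "token_span": list(ne.entity.token_span),
                        "term_id": ne.entity.term_id,
                        "polarity": ne.entity.polarity,
                        "link_method": ne.entity.link_method,
                        "similarity": ne.entity.similarity,
                    }
                    for ne in note_entities
                ],
            }
            fh.write(json.dumps(d, sort_keys=True) + "\n")
            n += 1
    return n


def read_entities(path) -> Iterator[tuple[str, list[NoteEntity]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            ents = [
                NoteEntity(
                    note_index=e["note_index"],
                    entity=ExtractedEntity(
                        sentence_index=e["sentence_index"],
                        token_span=tuple(e["token_span"]),
                        term_id=e["term_id"],
                        polarity=e["polarity"],
                        link_method=e["link_method"],
                        similarity=e["similarity"],
                    ),
                )
                for e in d["entities"]
            ]
            yield d["patient_id"], ents


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)


def read_scores_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _json_default(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {obj!r}")


def write_report(report: dict, path) -> None:
    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, float) and math.isnan(x):
            return None
        return x

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(clean(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
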