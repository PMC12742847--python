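"""Readers and writers for the on-disk formats.

Everything is plain text for diffability: knowledge graphs as a typed
edge-list TSV plus a node-table CSV, documents as JSON lines, patient tables
as five CSVs mirroring the MIMIC table roles, omics matrices as CSV with a
sample-metadata sidecar, ground truth as JSON.  Every writer's output passes
its own reader's validation, and write-then-read is the identity on the data
model.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ehr import PatientRecord
from .kg import KnowledgeGraph, Triplet
from .linkpred import EmbeddingTable
from .synthetic import GroundTruth
from .textmine import Document, Mention

EDGE_COLUMNS = ["head_id", "head_type", "relation", "tail_id", "tail_type",
                "weight", "score", "provenance"]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# knowledge graphs
# ---------------------------------------------------------------------------

def write_kg(kg: KnowledgeGraph, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        sorted(kg.node_types.items()), columns=["node_id", "node_type"]
    )
    nodes.to_csv(out / "nodes.csv", index=False)
    with open(out / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in sorted(kg.edges, key=lambda e: (e.key, e.weight)):
            score = "" if e.score is None else repr(e.score)
            fh.write(
                "\t".join(
                    [e.head, e.head_type, e.relation, e.tail, e.tail_type,
                     repr(e.weight), score, ";".join(e.provenance)]
                ) + "\n"
            )


def read_kg(in_dir) -> KnowledgeGraph:
    path = Path(in_dir)
    nodes = pd.read_csv(path / "nodes.csv", dtype=str)
    kg = KnowledgeGraph()
    for _, row in nodes.iterrows():
        kg.add_node(row["node_id"], row["node_type"])
    edge_path = path / "edges.tsv"
    with open(edge_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != EDGE_COLUMNS:
            raise ParseError(f"{edge_path}: line 1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(EDGE_COLUMNS):
                raise ParseError(
                    f"{edge_path}: line {lineno}: expected "
                    f"{len(EDGE_COLUMNS)} columns, got {len(parts)}"
                )
            head, head_type, relation, tail, tail_type, weight, score, prov = parts
            for endpoint in (head, tail):
                if endpoint not in kg.node_types:
                    raise ParseError(
                        f"{edge_path}: line {lineno}: edge endpoint "
                        f"{endpoint!r} missing from the node table"
                    )
            kg.add_edge(
                Triplet(
                    head=head, relation=relation, tail=tail,
                    head_type=head_type, tail_type=tail_type,
                    weight=float(weight),
                    score=None if score == "" else float(score),
                    provenance=tuple(p for p in prov.split(";") if p),
                )
            )
    return kg


# ---------------------------------------------------------------------------
# documents (JSON lines)
# ---------------------------------------------------------------------------

def write_documents(docs: list[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps({
                "id": doc.doc_id,
                "sentences": doc.sentences,
                "mentions": [
                    [m.sentence_index, m.surface, m.entity_id, m.entity_type]
                    for m in doc.mentions
                ],
            }, sort_keys=True) + "\n")


def read_documents(path) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            doc = Document(
                doc_id=d["id"],
                sentences=list(d["sentences"]),
                mentions=[Mention(*m) for m in d.get("mentions", [])],
            )
            doc.validate()
            docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# patient tables (five MIMIC-style roles)
# ---------------------------------------------------------------------------

def write_patient_tables(records: list[PatientRecord], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, admissions, diagnoses, prescriptions, notes = [], [], [], [], []
    for r in records:
        patients.append({"subject_id": r.subject_id,
                         "gender": r.demographics["gender"],
                         "age": r.demographics["age"]})
        admissions.append({"subject_id": r.subject_id,
                           "ethnicity": r.demographics["ethnicity"],
                           "religion": r.demographics["religion"],
                           "marital_status": r.demographics["marital_status"],
                           "insurance": r.demographics["insurance"]})
        for code in r.diagnoses:
            diagnoses.append({"subject_id": r.subject_id, "icd9_code": code})
        for drug in r.drugs:
            prescriptions.append({"subject_id": r.subject_id, "drug": drug})
        notes.append({"subject_id": r.subject_id, "text": r.note_text})
    pd.DataFrame(patients, columns=["subject_id", "gender", "age"]).to_csv(
        out / "PATIENTS.csv", index=False)
    pd.DataFrame(admissions, columns=["subject_id", "ethnicity", "religion",
                                      "marital_status", "insurance"]).to_csv(
        out / "ADMISSIONS.csv", index=False)
    pd.DataFrame(diagnoses, columns=["subject_id", "icd9_code"]).to_csv(
        out / "DIAGNOSES_ICD.csv", index=False)
    pd.DataFrame(prescriptions, columns=["subject_id", "drug"]).to_csv(
        out / "PRESCRIPTIONS.csv", index=False)
    pd.DataFrame(notes, columns=["subject_id", "text"]).to_csv(
        out / "NOTEEVENTS.csv", index=False)


def read_patient_tables(in_dir) -> list[PatientRecord]:
    path = Path(in_dir)
    patients = pd.read_csv(path / "PATIENTS.csv", dtype={"subject_id": str})
    admissions = pd.read_csv(path / "ADMISSIONS.csv", dtype={"subject_id": str})
    diagnoses = pd.read_csv(path / "DIAGNOSES_ICD.csv",
                            dtype={"subject_id": str, "icd9_code": str})
    prescriptions = pd.read_csv(path / "PRESCRIPTIONS.csv", dtype={"subject_id": str})
    notes = pd.read_csv(path / "NOTEEVENTS.csv", dtype={"subject_id": str})

    adm = admissions.set_index("subject_id")
    dx = diagnoses.groupby("subject_id")["icd9_code"].apply(list)
    rx = prescriptions.groupby("subject_id")["drug"].apply(list)
    note = notes.set_index("subject_id")["text"]

    records = []
    for _, row in patients.iterrows():
        sid = row["subject_id"]
        a = adm.loc[sid]
        records.append(PatientRecord(
            subject_id=sid,
            demographics={
                "age": int(row["age"]), "gender": row["gender"],
                "ethnicity": a["ethnicity"], "religion": a["religion"],
                "marital_status": a["marital_status"], "insurance": a["insurance"],
            },
            diagnoses=list(dx.get(sid, [])),
            drugs=list(rx.get(sid, [])),
            note_text="" if sid not in note.index or pd.isna(note.get(sid)) else str(note[sid]),
        ))
    return records


# ---------------------------------------------------------------------------
# omics, embeddings, ground truth, run results
# ---------------------------------------------------------------------------

def write_omics(matrix: pd.DataFrame, groups: pd.Series,
                covariates: pd.DataFrame, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.rename_axis("sample_id").to_csv(out / "matrix.csv")
    meta = pd.DataFrame({"group": groups})
    meta = meta.join(covariates)
    meta.rename_axis("sample_id").to_csv(out / "samples.csv")


def read_omics(in_dir) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    path = Path(in_dir)
    matrix = pd.read_csv(path / "matrix.csv", index_col="sample_id")
    meta = pd.read_csv(path / "samples.csv", index_col="sample_id")
    if "group" not in meta.columns:
        raise ParseError(f"{path / 'samples.csv'}: missing 'group' column")
    groups = meta["group"]
    covariates = meta.drop(columns=["group"])
    return matrix, groups, covariates


def write_embeddings(table: EmbeddingTable, path) -> None:
    table.to_frame().to_csv(path)


def read_embeddings(path) -> EmbeddingTable:
    frame = pd.read_csv(path, index_col="node_id")
    return EmbeddingTable(node_ids=list(frame.index),
                          matrix=frame.to_numpy(dtype=float))


def write_ground_truth(gt: GroundTruth, path) -> None:
    Path(path).write_text(gt.to_json(), encoding="utf-8")


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text(encoding="utf-8"))


def write_run_results(rows: list[dict], path) -> None:
    """Per-run MRR rows: label, run, arm, mrr, seed."""
    pd.DataFrame(rows, columns=["label", "run", "arm", "mrr", "seed"]).to_csv(
        path, index=False)


def read_run_results(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"label", "run", "arm", "mrr"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return frame


def float_format_csv(frame: pd.DataFrame, path) -> None:
    """Write a result CSV with a stable float representation (repr round-trip)."""
    frame.to_csv(path, index=False, float_format="%.12g")


def write_triplets_tsv(triplets, path) -> None:
    rows = [
        {"head_id": t.head, "head_type": t.head_type, "relation": t.relation,
         "tail_id": t.tail, "tail_type": t.tail_type,
         "score": "" if t.score is None else t.score,
         "provenance": ";".join(t.provenance)}
        for t in triplets
    ]
    pd.DataFrame(rows, columns=["head_id", "head_type", "relation", "tail_id",
                                "tail_type", "score", "provenance"]).to_csv(
        path, sep="\t", index=False)
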