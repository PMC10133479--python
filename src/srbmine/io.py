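"""Readers and writers for the pipeline's plain-text artifact dialects.

Dialects:

* gene dictionary TSV — one record per row, ``|``-separated synonym and
  GO lists (``GO:0000103:biological_process``);
* corpus JSONL — one document per line:
  ``{"doc_id":…, "text":…, "annotations":[{"start":…,"end":…,"text":…,
  "locus_tag":…}]}``;
* presence/absence CSV — families as rows, genomes as columns;
* contiguity / truth / partition TSVs — simple two-or-more column tables.
"""

from __future__ import annotations

import json
from typing import Iterable

import pandas as pd

from .annotate import AnnotatedDocument, GeneDictionary, GeneRecord, Mention, build_dictionary

__all__ = [
    "write_dictionary",
    "read_dictionary",
    "write_corpus",
    "read_corpus",
    "write_matrix",
    "read_matrix",
    "write_contiguity",
    "read_contiguity",
    "write_truth_labels",
    "read_truth_labels",
]

_DICT_COLUMNS = ["locus_tag", "symbol", "synonyms", "product", "pathway", "go_terms"]


def write_dictionary(dictionary: GeneDictionary, path) -> None:
    rows = [
        {
            "locus_tag": r.locus_tag,
            "symbol": r.symbol,
            "synonyms": "|".join(r.synonyms),
            "product": r.product,
            "pathway": r.pathway,
            "go_terms": "|".join(f"{g}:{a}" for g, a in r.go_terms),
        }
        for r in dictionary.records.values()
    ]
    pd.DataFrame(rows, columns=_DICT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dictionary(path) -> GeneDictionary:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_DICT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dictionary table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        go_terms = []
        for item in filter(None, row.go_terms.split("|")):
            go_id, _, aspect = item.rpartition(":")
            go_terms.append((go_id, aspect))
        records.append(
            GeneRecord(
                locus_tag=row.locus_tag,
                symbol=row.symbol,
                synonyms=tuple(filter(None, row.synonyms.split("|"))),
                product=row.product,
                pathway=row.pathway,
                go_terms=tuple(go_terms),
            )
        )
    return build_dictionary(records)


def write_corpus(docs: Iterable[AnnotatedDocument], path) -> None:
    with open(path, "w") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "text": doc.text,
                        "annotations": [
                            {
                                "start": m.start,
                                "end": m.end,
                                "text": m.text,
                                "locus_tag": m.locus_tag,
                            }
                            for m in doc.mentions
                        ],
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_corpus(path) -> list[AnnotatedDocument]:
    docs = []
    with open(path) as fh:
        for line in filter(str.strip, fh):
            d = json.loads(line)
            docs.append(
                AnnotatedDocument(
                    doc_id=d["doc_id"],
                    text=d["text"],
                    mentions=[
                        Mention(a["start"], a["end"], a["text"], a["locus_tag"])
                        for a in d.get("annotations", [])
                    ],
                )
            )
    return docs


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index_label="family")


def read_matrix(path) -> pd.DataFrame:
    from .pangenome import load_matrix

    return load_matrix(path)


def write_contiguity(graph, path) -> None:
    pd.DataFrame(
        sorted((min(a, b), max(a, b)) for a, b in graph.edges),
        columns=["family_a", "family_b"],
    ).to_csv(path, sep="\t", index=False)


def read_contiguity(path, families):
    from .pangenome import load_contiguity

    return load_contiguity(path, families)


def write_truth_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(labels.items()), columns=["family", "label"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["family"], df["label"]))
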