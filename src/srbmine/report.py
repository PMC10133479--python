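"""Essentiality segregation report.

Joins per-gene pangenome partitions with pathway categories into the
pathway × {persistent, shell, cloud} segregation table, computes the
headline class percentages (2-decimal, half-up rounding so that printed
figures recompute exactly from the counts), translates partitions into
essentiality calls, and exports an ordered presence/absence matrix for
heatmap rendering.

Call taxonomy: persistent → essential; shell → conditionally-essential
(essential only under particular growth conditions, e.g. formate or
hydrogen as electron donor); cloud → environment-specific.  Per-gene
overrides from configuration annotate the rationale without changing the
deterministic partition → call mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "PARTITIONS",
    "CALL_BY_PARTITION",
    "SegregationTable",
    "EssentialityCall",
    "segregate",
    "call_essentiality",
    "heatmap_matrix",
]

PARTITIONS = ("persistent", "shell", "cloud")
CALL_BY_PARTITION = {
    "persistent": "essential",
    "shell": "conditionally-essential",
    "cloud": "environment-specific",
}


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SegregationTable:
    """Pathway × partition counts with totals and class percentages."""

    counts: pd.DataFrame  # index pathway, columns persistent/shell/cloud/total
    grand_total: int
    percentages: dict[str, float]  # partition -> % of grand total, 2 dp

    def to_csv(self, path) -> None:
        out = self.counts.copy()
        out.loc["TOTAL"] = out.sum()
        out.to_csv(path, index_label="pathway")


def _canonical_partition(label: str) -> str:
    """Collapse shell_1..shell_j onto shell for reporting."""
    if label in PARTITIONS:
        return label
    if label.startswith("shell"):
        return "shell"
    raise ValueError(f"unknown partition label {label!r}")


def segregate(
    gene_partitions: pd.DataFrame, pathway_map: dict[str, str] | None = None
) -> SegregationTable:
    """Tabulate genes per (pathway, partition) cell.

    ``gene_partitions`` needs ``gene`` and ``partition`` columns; the
    pathway comes from a ``pathway`` column or ``pathway_map``, defaulting
    to "uncategorized".  Unknown partition labels raise ``ValueError``.
    Percentages are per partition class over the grand total, rounded
    half-up to 2 decimals, always recomputed from the counts.
    """
    df = gene_partitions.copy()
    if "pathway" not in df.columns:
        df["pathway"] = [
            (pathway_map or {}).get(g, "uncategorized") for g in df["gene"]
        ]
    df["pathway"] = df["pathway"].fillna("uncategorized")
    df["partition"] = [_canonical_partition(p) for p in df["partition"]]
    pathways = list(dict.fromkeys(df["pathway"]))  # first-seen order
    counts = (
        df.pivot_table(
            index="pathway", columns="partition", values="gene", aggfunc="count",
            fill_value=0,
        )
        .reindex(pathways)
        .reindex(columns=list(PARTITIONS), fill_value=0)
        .astype(int)
    )
    counts["total"] = counts.sum(axis=1)
    grand = int(counts["total"].sum())
    percentages = {
        p: (_round2(100.0 * counts[p].sum() / grand) if grand else 0.0)
        for p in PARTITIONS
    }
    return SegregationTable(counts=counts, grand_total=grand, percentages=percentages)


@dataclass(frozen=True)
class EssentialityCall:
    gene: str
    pathway: str
    partition: str
    call: str
    note: str = ""


def call_essentiality(
    gene_partitions: pd.DataFrame,
    overrides: dict[str, str] | None = None,
) -> list[EssentialityCall]:
    """Map each gene's partition to an essentiality call.

    ``overrides`` attaches a condition note per gene (e.g. a shell gene
    flagged "formate-dependent"); a note naming an absent gene emits a
    warning.  The partition → call mapping itself is never overridden.
    """
    overrides = dict(overrides or {})
    present = set(gene_partitions["gene"])
    for gene in sorted(set(overrides) - present):
        warnings.warn(f"essentiality override names absent gene {gene}", stacklevel=2)
    calls = []
    for row in gene_partitions.itertuples(index=False):
        partition = _canonical_partition(row.partition)
        calls.append(
            EssentialityCall(
                gene=row.gene,
                pathway=getattr(row, "pathway", "uncategorized"),
                partition=partition,
                call=CALL_BY_PARTITION[partition],
                note=overrides.get(row.gene, ""),
            )
        )
    return calls


def heatmap_matrix(
    matrix: pd.DataFrame,
    families=None,
    partitions: pd.Series | None = None,
    render_to=None,
) -> pd.DataFrame:
    """Order the presence/absence matrix for heatmap display.

    Rows are restricted to ``families`` (default all) and ordered by
    (partition rank, presence frequency descending); columns by genome
    presence frequency descending.  Unknown families raise ``ValueError``.
    ``render_to`` optionally writes a PNG via matplotlib.
    """
    families = list(families) if families is not None else list(matrix.index)
    unknown = [f for f in families if f not in matrix.index]
    if unknown:
        raise ValueError(f"unknown families: {unknown[:5]}")
    sub = matrix.loc[families]
    rank = {p: i for i, p in enumerate(PARTITIONS)}
    key = pd.DataFrame(index=sub.index)
    if partitions is not None:
        key["rank"] = [
            rank[_canonical_partition(partitions.get(f, "cloud"))] for f in sub.index
        ]
    else:
        key["rank"] = 0
    key["freq"] = -sub.mean(axis=1)
    sub = sub.loc[key.sort_values(["rank", "freq"], kind="stable").index]
    sub = sub[sub.mean(axis=0).sort_values(ascending=False, kind="stable").index]
    if render_to is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, sub.shape[1] / 6), max(3, sub.shape[0] / 8))
        )
        ax.imshow(sub.to_numpy(), aspect="auto", cmap="Greens", vmin=0, vmax=1)
        ax.set_xlabel("genomes")
        ax.set_ylabel("gene families")
        fig.tight_layout()
        fig.savefig(render_to, dpi=120)
        plt.close(fig)
    return sub
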