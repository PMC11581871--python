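"""Run tables, replicate averages and flow (Sankey-style) edge lists.

The table shapes mirror the standard dual RNA-seq mapping report: one row per
(interaction, replicate, strategy, order) with the six category counts, whose
sum is always the number of processed read pairs.  "Mapped" counts the four
cleanly assigned categories only — two-side cross-mapped reads are not mapped
to a single organism and are excluded from the mapped percentage.

Replicate averages recompute percentages as mean count over mean processed
(not as a mean of row percentages), which is the only convention under which
averaged counts and averaged percentages stay mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import pandas as pd

from .errors import DataError
from .strategy import AssignmentOutcome, Category, Order, Strategy

CATEGORY_FIELDS = {
    Category.UNIQUE_HOST: "unique_host",
    Category.MULTI_HOST: "multi_host",
    Category.UNIQUE_PARASITE: "unique_parasite",
    Category.MULTI_PARASITE: "multi_parasite",
    Category.TWO_SIDE: "two_side",
    Category.UNMAPPED: "unmapped",
}


@dataclass(frozen=True)
class RunRow:
    interaction: str
    replicate: str
    strategy: str
    order: str
    processed: int
    unique_host: int
    multi_host: int
    unique_parasite: int
    multi_parasite: int
    two_side: int
    unmapped: int

    def __post_init__(self) -> None:
        total = (self.unique_host + self.multi_host + self.unique_parasite
                 + self.multi_parasite + self.two_side + self.unmapped)
        if total != self.processed:
            raise DataError(
                f"category counts sum to {total}, not processed={self.processed}")

    @property
    def mapped(self) -> int:
        """Reads cleanly assigned to one organism (two-side reads excluded)."""
        return (self.unique_host + self.multi_host
                + self.unique_parasite + self.multi_parasite)

    @property
    def mapped_percent(self) -> float:
        return round(100.0 * self.mapped / self.processed, 2) if self.processed else 0.0

    def percent(self, category_field: str, decimals: int = 2) -> float:
        """Percentage of processed reads in one category column.  Per-replicate
        tables print 2 decimals; per-category summaries print whole numbers."""
        if not self.processed:
            return 0.0
        value = 100.0 * getattr(self, category_field) / self.processed
        return round(value) if decimals == 0 else round(value, decimals)


@dataclass(frozen=True)
class ReplicateSummary:
    """Means over replicates, in reads and in millions (2-decimal rendering)."""

    interaction: str
    strategy: str
    order: str
    n_replicates: int
    processed_mean: float
    means: dict[str, float]           # category field -> mean count
    percents: dict[str, float]        # category field -> mean count / mean processed
    mapped_percent: float

    def millions(self, category_field: str) -> float:
        return round(self.means[category_field] / 1e6, 2)


def tabulate_run(outcomes: list[AssignmentOutcome], interaction: str = "",
                 replicate: str = "") -> RunRow:
    """Exact category tallies of one (strategy, order, replicate) run."""
    runs = {(o.strategy, o.order) for o in outcomes}
    if len(runs) > 1:
        raise DataError(f"outcomes mix several runs: {sorted(runs)}")
    strategy, order = next(iter(runs)) if runs else (Strategy.COMBINED, Order.NA)
    counts = {f: 0 for f in CATEGORY_FIELDS.values()}
    for o in outcomes:
        counts[CATEGORY_FIELDS[o.category]] += 1
    return RunRow(interaction=interaction, replicate=replicate,
                  strategy=strategy.value, order=order.value,
                  processed=len(outcomes), **counts)


def average_replicates(rows: list[RunRow]) -> ReplicateSummary:
    """Arithmetic means over replicate rows of one (interaction, strategy,
    order) group; percentages are mean count / mean processed."""
    if not rows:
        raise DataError("average_replicates needs at least one row")
    groups = {(r.interaction, r.strategy, r.order) for r in rows}
    if len(groups) > 1:
        raise DataError(f"rows mix several groups: {sorted(groups)}")
    n = len(rows)
    processed_mean = sum(r.processed for r in rows) / n
    means = {f: sum(getattr(r, f) for r in rows) / n
             for f in CATEGORY_FIELDS.values()}
    percents = {f: (100.0 * means[f] / processed_mean if processed_mean else 0.0)
                for f in CATEGORY_FIELDS.values()}
    mapped_mean = sum(r.mapped for r in rows) / n
    mapped_percent = 100.0 * mapped_mean / processed_mean if processed_mean else 0.0
    interaction, strategy, order = next(iter(groups))
    return ReplicateSummary(interaction=interaction, strategy=strategy, order=order,
                            n_replicates=n, processed_mean=processed_mean,
                            means=means, percents=percents,
                            mapped_percent=mapped_percent)


def flow_table(outcomes: list[AssignmentOutcome]
               ) -> list[tuple[str, str, float]]:
    """Sankey-style edge list (source, destination, reads in millions).

    Totals are conserved at every node: merged -> per-organism assignment
    groups -> unique/multi categories.  Weights are exact divisions by 1e6
    (render-side rounding is left to the consumer).
    """
    if not outcomes:
        return []
    row = tabulate_run(outcomes)
    m = 1e6
    edges: list[tuple[str, str, float]] = []
    host_total = row.unique_host + row.multi_host
    para_total = row.unique_parasite + row.multi_parasite
    if host_total:
        edges.append(("merged", "host_assigned", host_total / m))
        edges.append(("host_assigned", "unique_host", row.unique_host / m))
        edges.append(("host_assigned", "multi_host", row.multi_host / m))
    if para_total:
        edges.append(("merged", "parasite_assigned", para_total / m))
        edges.append(("parasite_assigned", "unique_parasite", row.unique_parasite / m))
        edges.append(("parasite_assigned", "multi_parasite", row.multi_parasite / m))
    if row.two_side:
        edges.append(("merged", "two_side", row.two_side / m))
    if row.unmapped:
        edges.append(("merged", "unmapped", row.unmapped / m))
    return edges


# ---------------------------------------------------------------------------
# TSV round trips
# ---------------------------------------------------------------------------

def rows_to_frame(rows: list[RunRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = {f.name: getattr(r, f.name) for f in fields(r)}
        rec["mapped"] = r.mapped
        rec["mapped_percent"] = r.mapped_percent
        recs.append(rec)
    return pd.DataFrame(recs)


def write_rows_tsv(rows: list[RunRow], path: str) -> None:
    rows_to_frame(rows).to_csv(path, sep="\t", index=False)


def read_rows_tsv(path: str) -> list[RunRow]:
    df = pd.read_csv(path, sep="\t", dtype={"interaction": str, "replicate": str})
    names = [f.name for f in fields(RunRow)]
    out = []
    for rec in df.to_dict("records"):
        kwargs = {n: rec[n] for n in names}
        for n in ("interaction", "replicate"):
            if pd.isna(kwargs[n]):
                kwargs[n] = ""
        out.append(RunRow(**kwargs))
    return out


def write_flow_tsv(edges: list[tuple[str, str, float]], path: str) -> None:
    pd.DataFrame(edges, columns=["source", "destination", "reads_millions"]) \
        .to_csv(path, sep="\t", index=False)
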