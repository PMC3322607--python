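"""Archive statistics store and percentile ranking.

Validation metrics for a whole archive of entries are kept in a
versioned, whitespace-delimited text store.  A new entry's metrics are
ranked against the whole archive (absolute percentile) and against the
cohort of entries closest in resolution (relative percentile, cohort
size 1000 by default).  Percentiles use the mid-rank tie convention and
higher always means better quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricDefinition", "ArchiveStatistics", "PercentileSet",
    "DEFAULT_METRICS", "build_archive_statistics",
    "percentile_rank", "relative_cohort", "compute_percentiles",
]

MISSING = "."


@dataclass(frozen=True)
class MetricDefinition:
    metric_id: str
    orientation: str          # lower_is_better | higher_is_better
    display_name: str

    def __post_init__(self):
        if self.orientation not in ("lower_is_better", "higher_is_better"):
            raise ValueError(f"bad orientation {self.orientation!r}")


#: default slider metrics; all oriented so that lower raw values are better
DEFAULT_METRICS = (
    MetricDefinition("r_free", "lower_is_better", "Rfree"),
    MetricDefinition("clashscore", "lower_is_better", "Clashscore"),
    MetricDefinition("rama_outlier_pct", "lower_is_better",
                     "Ramachandran outliers (%)"),
    MetricDefinition("rotamer_outlier_pct", "lower_is_better",
                     "Rotamer outliers (%)"),
    MetricDefinition("rsrz_outlier_pct", "lower_is_better",
                     "RSRZ outliers (%)"),
)


@dataclass
class ArchiveEntry:
    entry_id: str
    resolution: float
    metrics: dict[str, float] = field(default_factory=dict)


@dataclass
class ArchiveStatistics:
    """Versioned per-entry metric store (the percentile reference)."""
    version: str
    metrics: tuple[MetricDefinition, ...]
    entries: list[ArchiveEntry]

    def __len__(self):
        return len(self.entries)

    def metric(self, metric_id: str) -> MetricDefinition:
        for m in self.metrics:
            if m.metric_id == metric_id:
                return m
        raise KeyError(f"metric {metric_id!r} not defined in archive "
                       f"{self.version}")

    def to_text(self) -> str:
        lines = [f"# xrayval-archive version={self.version}"]
        for m in self.metrics:
            lines.append(f"# metric {m.metric_id} {m.orientation} "
                         f"{m.display_name}")
        lines.append("# columns: entry_id resolution "
                     + " ".join(m.metric_id for m in self.metrics))
        for e in self.entries:
            vals = " ".join(
                (f"{e.metrics[m.metric_id]:.6g}"
                 if m.metric_id in e.metrics else MISSING)
                for m in self.metrics)
            lines.append(f"{e.entry_id} {e.resolution:.6g} {vals}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ArchiveStatistics":
        version = None
        metrics: list[MetricDefinition] = []
        entries: list[ArchiveEntry] = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = line.lstrip("# ").split()
                if toks and toks[0].startswith("xrayval-archive"):
                    version = toks[1].split("=", 1)[1]
                elif toks and toks[0] == "metric":
                    metrics.append(MetricDefinition(
                        toks[1], toks[2], " ".join(toks[3:])))
                continue
            toks = line.split()
            e = ArchiveEntry(toks[0], float(toks[1]))
            for m, v in zip(metrics, toks[2:]):
                if v != MISSING:
                    e.metrics[m.metric_id] = float(v)
            entries.append(e)
        if version is None:
            raise ValueError("archive file has no version header")
        return cls(version, tuple(metrics), entries)


def build_archive_statistics(entries, metric_defs, version: str
                             ) -> ArchiveStatistics:
    """Validate and assemble an archive store, sorted by resolution.

    *entries* are (entry_id, resolution, {metric_id: value}) triples.
    Duplicate entry ids and metric ids absent from *metric_defs* are
    errors; every entry needs a positive resolution and at least one
    metric.
    """
    defs = tuple(metric_defs)
    known = {m.metric_id for m in defs}
    seen = set()
    recs = []
    for entry_id, resolution, metrics in entries:
        if entry_id in seen:
            raise ValueError(f"duplicate entry id {entry_id!r}")
        seen.add(entry_id)
        if resolution <= 0:
            raise ValueError(f"entry {entry_id}: resolution must be positive")
        if not metrics:
            raise ValueError(f"entry {entry_id}: no metrics")
        unknown = set(metrics) - known
        if unknown:
            raise ValueError(f"entry {entry_id}: unknown metrics {unknown}")
        recs.append(ArchiveEntry(entry_id, resolution, dict(metrics)))
    if not recs:
        raise ValueError("archive must contain at least one entry")
    recs.sort(key=lambda e: (e.resolution, e.entry_id))
    return ArchiveStatistics(version, defs, recs)


def percentile_rank(value: float, metric: MetricDefinition,
                    pool_values) -> float:
    """Mid-rank percentile of *value* within *pool_values*, 0-100.

    P = 100 (n_worse + 0.5 n_tied) / N, where "worse" follows the
    metric orientation, so a higher percentile always means better
    quality.
    """
    pool = np.asarray(list(pool_values), dtype=float)
    if pool.size == 0:
        raise ValueError("empty pool")
    if metric.orientation == "lower_is_better":
        n_worse = int(np.sum(pool > value))
    else:
        n_worse = int(np.sum(pool < value))
    n_tied = int(np.sum(pool == value))
    return 100.0 * (n_worse + 0.5 * n_tied) / pool.size


def relative_cohort(resolution: float, archive: ArchiveStatistics,
                    n: int = 1000, exclude_entry_id: str | None = None):
    """The min(n, archive size) entries closest in resolution to the query.

    Ties at the cut are broken by smaller resolution, then entry id;
    the result is deterministic.  *exclude_entry_id* drops the query
    entry itself when it is already archived.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    pool = [e for e in archive.entries if e.entry_id != exclude_entry_id]
    pool.sort(key=lambda e: (abs(e.resolution - resolution),
                             e.resolution, e.entry_id))
    return pool[:n]


@dataclass
class PercentileSet:
    """Per-metric raw values and their absolute/relative percentiles."""
    archive_version: str
    cohort_size: int
    per_metric: dict[str, dict] = field(default_factory=dict)
    # per_metric[id] = {raw, absolute, relative, cohort}


def compute_percentiles(entry_scores: dict[str, float], resolution: float,
                        archive: ArchiveStatistics, n: int = 1000,
                        exclude_entry_id: str | None = None) -> PercentileSet:
    """Absolute (whole-archive) and relative (resolution cohort) percentiles.

    Metrics with no value in the entry, or absent from every pool entry,
    are skipped (reported as not-ranked downstream).
    """
    cohort = relative_cohort(resolution, archive, n, exclude_entry_id)
    out = PercentileSet(archive.version, len(cohort))
    for m in archive.metrics:
        if m.metric_id not in entry_scores:
            continue
        value = entry_scores[m.metric_id]
        if value is None:
            continue
        abs_pool = [e.metrics[m.metric_id] for e in archive.entries
                    if m.metric_id in e.metrics
                    and e.entry_id != exclude_entry_id]
        rel_pool = [e.metrics[m.metric_id] for e in cohort
                    if m.metric_id in e.metrics]
        if not abs_pool or not rel_pool:
            continue
        out.per_metric[m.metric_id] = {
            "raw": float(value),
            "absolute": percentile_rank(value, m, abs_pool),
            "relative": percentile_rank(value, m, rel_pool),
            "cohort": len(rel_pool),
        }
    return out
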