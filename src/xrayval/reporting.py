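"""Aggregation of per-residue scores and report rendering.

Per-residue geometry and density-fit results are pooled to chain and
entry level (entry percentages pool residues across chains rather than
averaging chain percentages).  The report is emitted as XML validating
against the shipped schema, plus a human-readable fixed-width slider
summary of the percentile ranks.  XML output is deterministic: identical
inputs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from lxml import etree

from .model_io import Structure
from .ranking import PercentileSet, DEFAULT_METRICS

__all__ = [
    "ChainScores", "EntryScores", "ValidationReport",
    "aggregate_scores", "render_xml", "parse_xml_scores", "render_sliders",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"
SLIDER_WIDTH = 50


@dataclass
class ChainScores:
    chain_id: str
    n_rama_evaluated: int = 0
    n_rama_outliers: int = 0
    n_rotamer_evaluated: int = 0
    n_rotamer_outliers: int = 0
    n_rsrz_evaluated: int = 0
    n_rsrz_outliers: int = 0
    rsr_values: list = field(default_factory=list)
    n_atoms: int = 0
    n_clashes: int = 0

    @staticmethod
    def _pct(num, den):
        return 100.0 * num / den if den else None

    @property
    def rama_outlier_pct(self):
        return self._pct(self.n_rama_outliers, self.n_rama_evaluated)

    @property
    def rotamer_outlier_pct(self):
        return self._pct(self.n_rotamer_outliers, self.n_rotamer_evaluated)

    @property
    def rsrz_outlier_pct(self):
        return self._pct(self.n_rsrz_outliers, self.n_rsrz_evaluated)

    @property
    def mean_rsr(self):
        vals = [v for v in self.rsr_values if v is not None]
        return sum(vals) / len(vals) if vals else None

    @property
    def clashscore(self):
        return 1000.0 * self.n_clashes / self.n_atoms if self.n_atoms else None


@dataclass
class EntryScores:
    entry: ChainScores
    chains: list[ChainScores]
    data: object | None = None      # DataCheckResult


def aggregate_scores(s: Structure, rama=None, rotamers=None, clashes=None,
                     fit_scores=None, data_result=None,
                     n_atoms_with_h: int | None = None) -> EntryScores:
    """Pool per-residue scores to chain and entry level.

    Percentages are computed over evaluated residues only (undefined and
    not-evaluated results stay out of the denominators; waters are never
    evaluated).  The entry block pools residues across chains.  The clash
    atom counts include placed hydrogens when *n_atoms_with_h* is given.
    """
    by_chain: dict[str, ChainScores] = {
        ch.chain_id: ChainScores(ch.chain_id) for ch in s.chains}
    entry = ChainScores("entry")

    chain_atoms: dict[str, int] = {}
    for ch in s.chains:
        chain_atoms[ch.chain_id] = sum(len(r.atoms) for r in ch.residues)
    total_atoms = n_atoms_with_h if n_atoms_with_h is not None \
        else sum(chain_atoms.values())
    entry.n_atoms = total_atoms
    for cid, cs in by_chain.items():
        cs.n_atoms = chain_atoms[cid]

    for res, phi, psi, label in (rama or []):
        if label in ("favored", "allowed", "outlier"):
            cs = by_chain[res.chain_id]
            cs.n_rama_evaluated += 1
            entry.n_rama_evaluated += 1
            if label == "outlier":
                cs.n_rama_outliers += 1
                entry.n_rama_outliers += 1
    for res, result in (rotamers or []):
        if result is not None:
            cs = by_chain[res.chain_id]
            cs.n_rotamer_evaluated += 1
            entry.n_rotamer_evaluated += 1
            if result[2]:
                cs.n_rotamer_outliers += 1
                entry.n_rotamer_outliers += 1
    for fs in (fit_scores or []):
        cs = by_chain[fs.residue.chain_id]
        if fs.rsr is not None:
            cs.rsr_values.append(fs.rsr)
            entry.rsr_values.append(fs.rsr)
        if fs.rsrz is not None:
            cs.n_rsrz_evaluated += 1
            entry.n_rsrz_evaluated += 1
            if fs.rsrz_outlier:
                cs.n_rsrz_outliers += 1
                entry.n_rsrz_outliers += 1
    for clash in (clashes or []):
        entry.n_clashes += 1
        involved = {clash.res1.chain_id, clash.res2.chain_id}
        for cid in involved:
            if cid in by_chain:
                by_chain[cid].n_clashes += 1
    return EntryScores(entry, list(by_chain.values()), data_result)


@dataclass
class ValidationReport:
    entry_id: str
    resolution: float | None
    tool_version: str
    archive_version: str | None
    scores: EntryScores
    percentiles: PercentileSet | None
    residue_rows: list = field(default_factory=list)
    # residue_rows: dicts with chain/name/seq/icode and optional metrics
    config_hash: str | None = None
    seed: int | None = None
    metric_defs: tuple = DEFAULT_METRICS


def _fmt(x, nd=3):
    return f"{x:.{nd}f}"


def _set_scores(el, cs: ChainScores):
    # absence of an attribute means not-evaluated, never 0
    if cs.rama_outlier_pct is not None:
        el.set("rama_outlier_pct", _fmt(cs.rama_outlier_pct))
    if cs.rotamer_outlier_pct is not None:
        el.set("rotamer_outlier_pct", _fmt(cs.rotamer_outlier_pct))
    if cs.clashscore is not None:
        el.set("clashscore", _fmt(cs.clashscore))
    if cs.rsrz_outlier_pct is not None:
        el.set("rsrz_outlier_pct", _fmt(cs.rsrz_outlier_pct))
    if cs.mean_rsr is not None:
        el.set("mean_rsr", _fmt(cs.mean_rsr))
    el.set("n_rama_evaluated", str(cs.n_rama_evaluated))
    el.set("n_rotamer_evaluated", str(cs.n_rotamer_evaluated))
    el.set("n_rsrz_evaluated", str(cs.n_rsrz_evaluated))
    el.set("n_atoms", str(cs.n_atoms))


def _schema() -> etree.XMLSchema:
    text = resources.files("xrayval.data").joinpath(
        "report_schema.xsd").read_bytes()
    return etree.XMLSchema(etree.fromstring(text))


def render_xml(report: ValidationReport, validate: bool = True) -> str:
    """Serialise the report as schema-valid XML.

    Element order is fixed and numbers use 3 decimals, so identical
    reports render byte-identically.  Not-evaluated quantities appear as
    absent attributes.  With *validate*, the output is checked against
    the shipped schema before being returned.
    """
    root = etree.Element("validation_report")
    root.set("id", report.entry_id)
    if report.resolution is not None:
        root.set("resolution", _fmt(report.resolution))
    root.set("tool_version", report.tool_version)
    if report.archive_version is not None:
        root.set("archive_version", report.archive_version)
    if report.config_hash is not None:
        root.set("config_hash", report.config_hash)
    if report.seed is not None:
        root.set("seed", str(report.seed))
    root.set("schema_version", SCHEMA_VERSION)

    summary = etree.SubElement(root, "summary")
    entry_el = etree.SubElement(summary, "entry")
    _set_scores(entry_el, report.scores.entry)
    for cs in report.scores.chains:
        ch_el = etree.SubElement(summary, "chain")
        ch_el.set("id", cs.chain_id)
        _set_scores(ch_el, cs)

    data = report.scores.data
    if data is not None:
        d = etree.SubElement(root, "data_checks")
        if data.r is not None:
            d.set("r", _fmt(data.r))
        if data.r_free is not None:
            d.set("r_free", _fmt(data.r_free))
        if data.scale_k is not None:
            d.set("scale_k", _fmt(data.scale_k))
        if data.wilson is not None:
            d.set("wilson_b", _fmt(data.wilson.b))
        if data.moments is not None:
            d.set("moment_ratio", _fmt(data.moments.ratio))
            d.set("mislabel_verdict", data.moments.verdict)
        if data.ltest is not None:
            d.set("l_mean", _fmt(data.ltest.l_mean))
            d.set("l_second", _fmt(data.ltest.l_second))
            d.set("twin_verdict", data.ltest.verdict)
        d.set("n_outlier_reflections", str(len(data.outlier_hkls)))

    p = etree.SubElement(root, "percentiles")
    if report.percentiles is not None:
        p.set("archive_version", report.percentiles.archive_version)
        for m in report.metric_defs:
            m_el = etree.SubElement(p, "metric")
            m_el.set("id", m.metric_id)
            rec = report.percentiles.per_metric.get(m.metric_id)
            if rec is None:
                m_el.set("ranked", "false")   # explicit not-ranked marker
            else:
                m_el.set("raw", _fmt(rec["raw"]))
                m_el.set("absolute", _fmt(rec["absolute"]))
                m_el.set("relative", _fmt(rec["relative"]))
                m_el.set("cohort", str(rec["cohort"]))

    chains_el = etree.SubElement(root, "chains")
    by_chain: dict[str, etree._Element] = {}
    for row in report.residue_rows:
        cid = row["chain"]
        if cid not in by_chain:
            ch = etree.SubElement(chains_el, "chain")
            ch.set("id", cid)
            by_chain[cid] = ch
        r = etree.SubElement(by_chain[cid], "residue")
        r.set("name", row["name"])
        r.set("seq", str(row["seq"]))
        if row.get("icode"):
            r.set("icode", row["icode"])
        for key in ("rama", "rotamer"):
            if row.get(key) is not None:
                r.set(key, str(row[key]))
        for key in ("rotamer_dev", "rsr", "rsrz", "geom_max_z"):
            if row.get(key) is not None:
                r.set(key, _fmt(row[key]))
        if row.get("clashes") is not None:
            r.set("clashes", str(row["clashes"]))

    text = etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8")
    if validate:
        schema = _schema()
        doc = etree.fromstring(text)
        if not schema.validate(doc):
            raise RuntimeError(
                f"internal error: report fails schema: {schema.error_log}")
    return text.decode()


def parse_xml_scores(text: str) -> dict:
    """Parse back a rendered report into plain dicts (round-trip checks)."""
    root = etree.fromstring(text.encode())
    out = {"entry": dict(root.find("summary/entry").attrib),
           "chains": {}, "residues": [], "attrib": dict(root.attrib)}
    for ch in root.findall("summary/chain"):
        out["chains"][ch.get("id")] = dict(ch.attrib)
    for ch in root.findall("chains/chain"):
        for r in ch.findall("residue"):
            d = dict(r.attrib)
            d["chain"] = ch.get("id")
            out["residues"].append(d)
    dc = root.find("data_checks")
    out["data_checks"] = dict(dc.attrib) if dc is not None else None
    out["percentiles"] = {
        m.get("id"): dict(m.attrib)
        for m in root.findall("percentiles/metric")}
    return out


def slider_column(p: float, width: int = SLIDER_WIDTH) -> int:
    """1-based marker column for percentile p on a fixed-width bar."""
    return int(round(p / 100.0 * (width - 1))) + 1


def render_sliders(p: PercentileSet, metric_defs=DEFAULT_METRICS) -> str:
    """Fixed-width text sliders: worse on the left, better on the right.

    Each metric line shows the raw value and a 50-character bar with
    ``A`` at the absolute percentile and ``R`` at the relative one
    (``*`` where they coincide).
    """
    if not p.per_metric:
        raise ValueError("empty percentile set")
    lines = [f"Percentile ranks (archive {p.archive_version}; "
             f"cohort up to {p.cohort_size} entries)",
             f"{'metric':<28}{'raw':>10}  worse {'':{SLIDER_WIDTH - 12}}better"]
    for m in metric_defs:
        rec = p.per_metric.get(m.metric_id)
        if rec is None:
            lines.append(f"{m.display_name:<28}{'--':>10}  [not ranked]")
            continue
        bar = ["-"] * SLIDER_WIDTH
        ca = slider_column(rec["absolute"]) - 1
        cr = slider_column(rec["relative"]) - 1
        bar[ca] = "A"
        bar[cr] = "*" if cr == ca else "R"
        lines.append(f"{m.display_name:<28}{rec['raw']:>10.3f}  |"
                     + "".join(bar) + "|")
    lines.append("A = absolute percentile, R = relative (resolution cohort), "
                 "* = both")
    return "\n".join(lines) + "\n"
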