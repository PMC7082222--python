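"""Snapshot, diff and history reports (self-contained HTML + JSON)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from jinja2 import Template

from .config import Config
from .results import ResultSet
from .scoring import compute_score

__all__ = ["ReportDocument", "snapshot_report", "diff_report", "history_report"]

DELTA_TOLERANCE = 1e-9

_STYLE = """
body { font-family: sans-serif; margin: 2em; color: #222; }
h1 { border-bottom: 2px solid #446; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #bbb; padding: 0.3em 0.6em; text-align: left; }
th { background: #eef; }
.metric-bad { background: #fdd; }
.metric-good { background: #dfd; }
.delta { background: #ffd; font-weight: bold; }
.unscored { color: #888; }
"""


@dataclass
class ReportDocument:
    html: str
    data: dict

    def write(self, html_path: Optional[str] = None, json_path: Optional[str] = None) -> None:
        if html_path:
            with open(html_path, "w", encoding="utf-8") as handle:
                handle.write(self.html)
        if json_path:
            with open(json_path, "w", encoding="utf-8") as handle:
                json.dump(self.data, handle, indent=2, sort_keys=True)


_SNAPSHOT = Template("""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>gemaudit snapshot — {{ rs.model_id }}</title>
<style>{{ style }}</style></head><body>
<h1>Model QC snapshot: {{ rs.model_id }}</h1>
<p>digest <code>{{ rs.digest[:16] }}…</code> · run {{ rs.timestamp }} · gemaudit {{ rs.tool_version }}</p>
<h2>Overall score: {{ "%.1f" % score.overall if score.overall is not none else "undefined" }} / 100</h2>
<table><tr><th>Section</th><th>Weight</th><th>Score</th></tr>
{% for section, value in score.sections | dictsort %}
<tr><td>{{ section }}</td><td>{{ score.section_weights[section] }}</td>
<td>{{ "%.1f" % value }}</td></tr>
{% endfor %}</table>
{% for section in sections %}
<h2>{{ section }}</h2>
<table><tr><th>Test</th><th>Metric</th><th>Offenders</th><th>Message</th></tr>
{% for r in rs.results if r.section == section %}
<tr class="{{ 'unscored' if r.metric is none else ('metric-good' if r.metric > 0.999 else 'metric-bad') }}">
<td>{{ r.test_id }}</td>
<td>{{ "%.3f" % r.metric if r.metric is not none else "—" }}</td>
<td>{{ r.data[:20] | join(", ") }}{{ " …" if r.data | length > 20 else "" }}</td>
<td>{{ r.message }}</td></tr>
{% endfor %}</table>
{% endfor %}
<h2>Configuration</h2><pre>{{ config_echo }}</pre>
</body></html>
""")


def _config_echo(config: Config) -> dict:
    return {
        "tolerances": {
            "big_m": config.big_m, "eps_y": config.eps_y, "eps_flux": config.eps_flux,
            "eps_growth": config.eps_growth, "biomass_tolerance": config.biomass_tolerance,
            "open_bound": config.open_bound,
        },
        "section_weights": dict(config.section_weights),
        "test_weights": dict(config.test_weights),
    }


def snapshot_report(result_set: ResultSet, config: Optional[Config] = None) -> ReportDocument:
    """Human-readable snapshot plus a machine-readable payload.

    The JSON payload round-trips the result set (so a report file can be
    diffed later) and echoes the score breakdown and configuration.
    """
    config = config or Config()
    score = compute_score(result_set, config)
    sections = sorted({r.section for r in result_set.results})
    html = _SNAPSHOT.render(rs=result_set, score=score, sections=sections,
                            style=_STYLE, config_echo=json.dumps(_config_echo(config),
                                                                 indent=2, sort_keys=True))
    data = {
        "result_set": result_set.to_dict(),
        "score": {
            "overall": score.overall,
            "sections": score.sections,
            "section_weights": score.section_weights,
            "unscored_tests": score.unscored_tests,
        },
        "config": _config_echo(config),
    }
    return ReportDocument(html=html, data=data)


_DIFF = Template("""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>gemaudit diff</title>
<style>{{ style }}</style></head><body>
<h1>Model comparison ({{ models | length }} models)</h1>
<table><tr><th>Model</th><th>Digest</th><th>Overall score</th></tr>
{% for m in models %}<tr><td>{{ m.label }}</td><td><code>{{ m.digest[:16] }}…</code></td>
<td>{{ "%.1f" % m.overall if m.overall is not none else "undefined" }}</td></tr>{% endfor %}
</table>
<h2>Per-test metrics</h2>
<table><tr><th>Test</th>{% for m in models %}<th>{{ m.label }}</th>{% endfor %}</tr>
{% for row in rows %}
<tr><td>{{ row.test_id }}</td>
{% for value in row.metrics %}
<td class="{{ 'delta' if row.changed else '' }}">{{ "%.3f" % value if value is not none else "—" }}</td>
{% endfor %}</tr>
{% endfor %}</table>
</body></html>
""")


def diff_report(result_sets: Sequence[ResultSet],
                config: Optional[Config] = None) -> ReportDocument:
    """Side-by-side metrics for two or more result sets.

    A row is highlighted when any pair of models disagrees on the metric
    by more than 1e-9 (or on scored-ness).
    """
    if len(result_sets) < 2:
        raise ValueError("diff report needs at least two result sets")
    config = config or Config()
    labels = []
    seen: Dict[str, int] = {}
    for rs in result_sets:
        count = seen.get(rs.model_id, 0)
        seen[rs.model_id] = count + 1
        labels.append(rs.model_id if count == 0 else f"{rs.model_id}#{count + 1}")
    test_ids: List[str] = []
    for rs in result_sets:
        for result in rs.results:
            if result.test_id not in test_ids:
                test_ids.append(result.test_id)
    rows = []
    changed_tests = []
    for test_id in test_ids:
        metrics = []
        for rs in result_sets:
            try:
                metrics.append(rs.get(test_id).metric)
            except KeyError:
                metrics.append(None)
        first = metrics[0]
        changed = any(
            (m is None) != (first is None)
            or (m is not None and first is not None and abs(m - first) > DELTA_TOLERANCE)
            for m in metrics[1:]
        )
        if changed:
            changed_tests.append(test_id)
        rows.append({"test_id": test_id, "metrics": metrics, "changed": changed})
    models = []
    for rs, label in zip(result_sets, labels):
        score = compute_score(rs, config)
        models.append({"label": label, "digest": rs.digest, "overall": score.overall})
    html = _DIFF.render(models=models, rows=rows, style=_STYLE)
    data = {
        "models": models,
        "changed_tests": changed_tests,
        "metrics": {row["test_id"]: row["metrics"] for row in rows},
    }
    return ReportDocument(html=html, data=data)


_HISTORY = Template("""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>gemaudit history</title>
<style>{{ style }}</style></head><body>
<h1>Score history: {{ model_id }}</h1>
{% if collapsed %}<p>{{ collapsed }} duplicate model version(s) collapsed (identical digest).</p>{% endif %}
<table><tr><th>#</th><th>Timestamp</th><th>Digest</th><th>Overall score</th></tr>
{% for point in trajectory %}
<tr><td>{{ loop.index }}</td><td>{{ point.timestamp }}</td>
<td><code>{{ point.digest[:16] }}…</code></td>
<td>{{ "%.1f" % point.overall if point.overall is not none else "undefined" }}</td></tr>
{% endfor %}</table>
</body></html>
""")


def history_report(result_sets: Sequence[ResultSet],
                   config: Optional[Config] = None,
                   ordered: bool = False) -> ReportDocument:
    """Score trajectory over an ordered sequence of model versions.

    Without ``ordered`` the sets are sorted by timestamp; consecutive
    duplicates (identical digest) are collapsed with a note.
    """
    if not result_sets:
        raise ValueError("history report needs at least one result set")
    config = config or Config()
    sets = list(result_sets) if ordered else sorted(result_sets, key=lambda rs: rs.timestamp)
    trajectory = []
    collapsed = 0
    for rs in sets:
        if trajectory and trajectory[-1]["digest"] == rs.digest:
            collapsed += 1
            continue
        score = compute_score(rs, config)
        trajectory.append({
            "digest": rs.digest,
            "timestamp": rs.timestamp,
            "overall": score.overall,
            "sections": score.sections,
            "metrics": {r.test_id: r.metric for r in rs.results},
        })
    html = _HISTORY.render(model_id=sets[0].model_id, trajectory=trajectory,
                           collapsed=collapsed, style=_STYLE)
    test_ids = sorted(trajectory[0]["metrics"]) if trajectory else []
    data = {
        "model_id": sets[0].model_id,
        "collapsed_duplicates": collapsed,
        "trajectory": [
            {k: v for k, v in point.items() if k != "metrics"} for point in trajectory
        ],
        "per_test": {
            tid: [point["metrics"].get(tid) for point in trajectory] for tid in test_ids
        },
    }
    return ReportDocument(html=html, data=data)
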