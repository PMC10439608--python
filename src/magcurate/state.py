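"""Session state: checkpointing, logging, and exports.

A :class:`Session` bundles the contig table, any number of binning plans,
view settings (active columns and their transforms, the current
selection) and a structured operation log. Sessions serialize losslessly
to a versioned JSON checkpoint; replaying the logged plan edits on the
initial inputs reproduces the final assignments.
"""

from __future__ import annotations

import datetime
import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .binning import BinningPlan, edit_plan, write_plan_tsv
from .ingest import write_table
from .table import ColumnKind, ColumnSpec, ContigTable
from .transforms import transform_values

__all__ = [
    "Session",
    "CheckpointError",
    "FORMAT_VERSION",
    "save_checkpoint",
    "load_checkpoint",
    "export_bins",
    "export_scatter",
    "replay_plan_edits",
]

FORMAT_VERSION = 1


class CheckpointError(ValueError):
    """Raised on unreadable or incompatible checkpoint files."""


@dataclass
class Session:
    table: ContigTable
    plans: dict[str, BinningPlan] = field(default_factory=dict)
    view: dict = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    def add_plan(self, plan: BinningPlan) -> None:
        self.plans[plan.name] = plan

    def log_event(self, op: str, **params) -> dict:
        """Append a structured, timestamped log entry and return it."""
        entry = {
            "time": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "op": op,
            "params": params,
        }
        self.log.append(entry)
        return entry

    def edit_plan(self, plan_name: str, action: str, **args) -> BinningPlan:
        """Apply a plan edit and log it (the logged form is replayable)."""
        plan = self.plans[plan_name]
        edit_plan(plan, action, **args)
        self.log_event("edit_plan", plan=plan_name, action=action, **_jsonable(args))
        return plan

    def write_log(self, path) -> None:
        """Dump the log as JSON lines."""
        with Path(path).open("w", encoding="utf-8") as fh:
            for entry in self.log:
                fh.write(json.dumps(_jsonable(entry)) + "\n")


def replay_plan_edits(session: Session, log: Sequence[Mapping]) -> Session:
    """Re-apply logged ``edit_plan`` entries onto a session's plans."""
    for entry in log:
        if entry.get("op") != "edit_plan":
            continue
        params = dict(entry["params"])
        plan_name = params.pop("plan")
        action = params.pop("action")
        edit_plan(session.plans[plan_name], action, **params)
    return session


# -- JSON (de)serialization -------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def _serialize_table(table: ContigTable) -> dict:
    cols = []
    for name in table.columns:
        spec = table.spec(name)
        values = []
        for v in table.values(name):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                values.append(None)
            elif isinstance(v, Counter):
                values.append(dict(v))
            else:
                values.append(v)
        cols.append({"name": name, "kind": spec.kind.value, "values": values})
    return {
        "ids": list(table.ids),
        "columns": cols,
        "mask": table.mask.astype(int).tolist(),
        "highlight": table.highlight.tolist(),
    }


def _deserialize_table(payload: dict) -> ContigTable:
    table = ContigTable(payload["ids"])
    for col in payload["columns"]:
        kind = ColumnKind(col["kind"])
        values = []
        for v in col["values"]:
            if v is None:
                values.append(math.nan if kind is ColumnKind.NUMERIC else None)
            elif kind is ColumnKind.FEATURE_SET:
                values.append(Counter(v))
            elif kind is ColumnKind.NUMERIC:
                values.append(float(v))
            else:
                values.append(v)
        table.add_column(ColumnSpec(col["name"], kind), values)
    table.mask = np.asarray(payload["mask"], dtype=bool)
    table.highlight = np.asarray(payload["highlight"], dtype=np.int64)
    return table


def _serialize_plan(plan: BinningPlan) -> dict:
    return {
        "name": plan.name,
        "assignment": dict(plan.assignment),
        "bins": sorted(plan.bins),
        "history": _jsonable(plan.history),
    }


def _deserialize_plan(payload: dict) -> BinningPlan:
    history = []
    for rec in payload["history"]:
        rec = dict(rec)
        if rec["action"] == "delete":
            rec["members"] = set(rec["members"])
        history.append(rec)
    return BinningPlan(
        name=payload["name"],
        assignment=dict(payload["assignment"]),
        bins=set(payload["bins"]),
        history=history,
    )


def save_checkpoint(session: Session, path) -> None:
    """Serialize the full session to a versioned JSON checkpoint."""
    payload = {
        "format_version": FORMAT_VERSION,
        "table": _serialize_table(session.table),
        "plans": [_serialize_plan(p) for p in session.plans.values()],
        "view": _jsonable(session.view),
        "log": _jsonable(session.log),
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> Session:
    """Load a checkpoint; refuses unknown format versions outright."""
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise CheckpointError(f"{path.name}: not valid JSON ({exc})") from exc
    version = payload.get("format_version")
    if version is None:
        raise CheckpointError(f"{path.name}: missing required key 'format_version'")
    if not isinstance(version, int) or version > FORMAT_VERSION:
        raise CheckpointError(
            f"{path.name}: unsupported format_version {version!r} "
            f"(this build reads <= {FORMAT_VERSION})"
        )
    for key in ("table", "plans", "view", "log"):
        if key not in payload:
            raise CheckpointError(f"{path.name}: missing required key {key!r}")
    table = _deserialize_table(payload["table"])
    plans = {p["name"]: _deserialize_plan(p) for p in payload["plans"]}
    return Session(table=table, plans=plans, view=payload["view"], log=payload["log"])


# -- exports -----------------------------------------------------------

_SANITIZE_RE = re.compile(r"[^A-Za-z0-9._-]+")


def sanitize_name(name: str) -> str:
    out = _SANITIZE_RE.sub("_", name).strip("_")
    return out or "bin"


def export_bins(plan: BinningPlan, table: ContigTable, out_dir) -> dict[str, Path]:
    """Write one contig-data TSV per bin plus the 2-column plan TSV.

    File names derive from sanitized bin names; sanitization collisions
    abort with the colliding names listed. Masked contigs are omitted.
    Returns a mapping from bin name (plus ``"__plan__"``) to path.
    """
    if not plan.assignment:
        raise ValueError(f"plan {plan.name!r} is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sanitized = {b: sanitize_name(b) for b in sorted(plan.bins)}
    by_file: dict[str, list[str]] = {}
    for b, s in sanitized.items():
        by_file.setdefault(s, []).append(b)
    collisions = {s: bs for s, bs in by_file.items() if len(bs) > 1}
    if collisions:
        raise ValueError(f"bin names collide after sanitization: {collisions}")
    written: dict[str, Path] = {}
    for b, s in sanitized.items():
        members = sorted(
            cid for cid in plan.members(b) if cid in table and not table.is_masked(cid)
        )
        path = out_dir / f"{s}.tsv"
        write_table(table, path, ids=members)
        written[b] = path
    plan_path = out_dir / f"{sanitize_name(plan.name)}_plan.tsv"
    write_plan_tsv(plan, plan_path)
    written["__plan__"] = plan_path
    return written


def export_scatter(
    table: ContigTable,
    aesthetics: Mapping[str, str],
    path,
    *,
    plan: BinningPlan | None = None,
) -> None:
    """Render the contig scatter to a static PNG or SVG figure.

    *aesthetics* maps the five channels onto table columns:
    ``x``/``y`` (required, numeric), ``size``, ``opacity`` (numeric) and
    ``color`` (categorical; ignored when *plan* is given, which colors by
    bin instead). Optional ``<channel>_transform`` entries name a
    transform applied before scaling. Masked contigs are omitted;
    contigs draw in ascending ID order, and SVG output is byte-stable
    across runs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matplotlib.rcParams["svg.hashsalt"] = "magcurate"

    for channel in ("x", "y"):
        if channel not in aesthetics:
            raise ValueError(f"aesthetics must map {channel!r} to a numeric column")
    order = sorted(
        (i for i in range(len(table)) if not table.mask[i]),
        key=lambda i: table.ids[i],
    )

    def channel_values(channel: str) -> np.ndarray | None:
        col = aesthetics.get(channel)
        if col is None:
            return None
        vals = table.numeric(col)[order]
        method = aesthetics.get(f"{channel}_transform", "none")
        vals, _ = transform_values(vals, method)
        return vals

    x = channel_values("x")
    y = channel_values("y")
    size = channel_values("size")
    opacity = channel_values("opacity")

    def scale(vals, lo, hi, default):
        if vals is None:
            return np.full(len(order), default)
        vmin, vmax = np.nanmin(vals), np.nanmax(vals)
        if not np.isfinite(vmin) or vmax == vmin:
            return np.full(len(order), (lo + hi) / 2)
        out = lo + (hi - lo) * (vals - vmin) / (vmax - vmin)
        return np.where(np.isnan(out), lo, out)

    sizes = scale(size, 4.0, 80.0, 20.0)
    alphas = scale(opacity, 0.2, 1.0, 0.8)

    fig, ax = plt.subplots(figsize=(7, 6))
    if plan is not None:
        labels = [plan.assignment.get(table.ids[i]) for i in order]
    elif "color" in aesthetics:
        col = aesthetics["color"]
        labels = [table.values(col)[i] for i in order]
    else:
        labels = None
    if labels is None:
        ax.scatter(x, y, s=sizes, alpha=alphas, c="steelblue", edgecolors="none")
    else:
        uniq = sorted({lab for lab in labels if lab is not None})
        cmap = plt.get_cmap("tab10")
        colors = {lab: cmap(j % 10) for j, lab in enumerate(uniq)}
        keep_na = [j for j, lab in enumerate(labels) if lab is None]
        if keep_na:
            ax.scatter(
                x[keep_na], y[keep_na], s=sizes[keep_na], alpha=alphas[keep_na],
                c="lightgray", edgecolors="none", label="(unassigned)",
            )
        for lab in uniq:
            sel = [j for j, l in enumerate(labels) if l == lab]
            ax.scatter(
                x[sel], y[sel], s=sizes[sel], alpha=alphas[sel],
                c=[colors[lab]], edgecolors="none", label=str(lab),
            )
        ax.legend(loc="best", fontsize=7, markerscale=0.8)
    ax.set_xlabel(aesthetics["x"])
    ax.set_ylabel(aesthetics["y"])
    fig.tight_layout()
    fig.savefig(str(path), metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
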