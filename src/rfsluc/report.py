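"""Report rendering and run manifests.

Renders the indicator summary (one column per indicator, rows for the
rotation and extent components, CI limits when propagated, combined totals,
BAU baselines, and the two percent normalizations) and the fuel-intensity
comparison, as CSV plus one-decimal Markdown.  A run manifest records the
config hash, seed, package version, and digests of every written file so a
run can be reproduced byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import environment as env

_ROW_ORDER = [
    ("rotation_delta", "Crop rotation delta"),
    ("rot_lo", "  95% CI lower"),
    ("rot_hi", "  95% CI upper"),
    ("extent_delta", "Cropland extent delta"),
    ("ext_lo", "  95% CI lower"),
    ("ext_hi", "  95% CI upper"),
    ("combined", "Combined total delta"),
    ("comb_lo", "  95% CI lower"),
    ("comb_hi", "  95% CI upper"),
    ("bau_baseline", "BAU baseline"),
    ("pct_of_bau", "% change from BAU"),
    ("pct_per_bgy", "% change per BGY"),
]


def table1_grid(summary: env.Table1Summary,
                ci_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wide layout: indicators as columns, summary rows as rows."""
    t = summary.table.set_index("indicator")
    cols = {}
    for ind in t.index:
        label = env.INDICATOR_LABELS.get(ind, ind)
        col = {
            "rotation_delta": t.loc[ind, "rotation_delta"],
            "extent_delta": t.loc[ind, "extent_delta"],
            "combined": t.loc[ind, "combined"],
            "bau_baseline": t.loc[ind, "bau_baseline"],
            "pct_of_bau": t.loc[ind, "pct_of_bau"],
            "pct_per_bgy": t.loc[ind, "pct_per_bgy"],
        }
        if ci_table is not None:
            q = ci_table.set_index("quantity")
            for pre, key in (("rot", f"rot_{ind}"), ("ext", f"ext_{ind}"),
                             ("comb", f"comb_{ind}")):
                if key in q.index:
                    col[f"{pre}_lo"] = q.loc[key, "lo"]
                    col[f"{pre}_hi"] = q.loc[key, "hi"]
        cols[label] = col
    grid = pd.DataFrame(cols)
    keep = [k for k, _ in _ROW_ORDER if k in grid.index]
    grid = grid.loc[keep]
    grid.index = [lbl for k, lbl in _ROW_ORDER if k in keep]
    return grid


def _to_markdown(df: pd.DataFrame, index_label: str = "") -> str:
    def fmt(v):
        if isinstance(v, (int, float)):
            return "" if pd.isna(v) else f"{v:,.1f}"
        return str(v)
    header = [index_label] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(["---"] * len(header)) + "|"]
    for idx, row in df.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [fmt(v) for v in row])
                     + " |")
    return "\n".join(lines) + "\n"


def render_report(outdir: str, summary: env.Table1Summary,
                  table2: pd.DataFrame,
                  ci_table: pd.DataFrame | None = None) -> list[str]:
    """Write table1/table2 as CSV and Markdown; returns the file list."""
    os.makedirs(outdir, exist_ok=True)
    written = []
    grid = table1_grid(summary, ci_table)
    p = os.path.join(outdir, "table1.csv")
    grid.to_csv(p)
    written.append(p)
    p = os.path.join(outdir, "table1.md")
    with open(p, "w", encoding="utf-8") as fh:
        fh.write(_to_markdown(grid, "Quantity"))
    written.append(p)
    p = os.path.join(outdir, "table2.csv")
    table2.to_csv(p, index=False)
    written.append(p)
    p = os.path.join(outdir, "table2.md")
    with open(p, "w", encoding="utf-8") as fh:
        fh.write(_to_markdown(table2.set_index("program"), "Program"))
    written.append(p)
    return written


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""
    config_hash: str
    seed: int
    version: str
    files: dict[str, str] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def add_file(self, path: str) -> None:
        with open(path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        self.files[os.path.basename(path)] = digest

    def note(self, msg: str) -> None:
        self.log.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}")

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "files": self.files,
                "log": self.log,
            }, fh, sort_keys=False)


def config_hash(config) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()
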