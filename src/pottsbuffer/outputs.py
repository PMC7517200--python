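"""Run archiving: config echo, per-trial labels, aggregate tables, summaries.

Everything is written as plain text (JSON / tab-separated tables) at full
floating-point precision, so a run archive round-trips bit-exactly and
re-running from the archived config and seed reproduces the aggregates.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .analysis import CATEGORIES
from .config import ExperimentConfig
from .production import BatchResult

__all__ = ["error_table", "write_outputs", "read_summary", "write_trajectory"]


def error_table(result: BatchResult) -> pd.DataFrame:
    """Category percentages with SEM and first-error-position breakdown."""
    agg = result.aggregate
    rows = []
    for cat in CATEGORIES:
        pct, sem = agg["categories"][cat]
        counts = {
            f"first_error_pos{p}": sum(
                1 for r in result.records
                if r.label.category == cat and r.label.first_error_position == p
            )
            for p in (1, 2, 3)
        }
        rows.append({"category": cat, "percent": pct, "sem": sem, **counts})
    return pd.DataFrame(rows)


def write_outputs(result: BatchResult, config: ExperimentConfig, seed: int,
                  out_dir: str | Path) -> dict:
    """Write the error table, per-trial labels and a JSON summary; return the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = error_table(result)
    table.to_csv(out / "error_distribution.tsv", sep="\t", index=False, float_format="%.17g")

    trials = pd.DataFrame(
        {
            "item_index": [r.item_index for r in result.records],
            "item_kind": [r.item_kind for r in result.records],
            "target": [",".join(map(str, r.target)) for r in result.records],
            "uttered": [
                ",".join(str(u.pattern_id) for u in r.utterances) for r in result.records
            ],
            "category": [r.label.category for r in result.records],
            "first_error_position": [r.label.first_error_position for r in result.records],
            "n_utterances": [r.n_utterances for r in result.records],
        }
    )
    trials.to_csv(out / "trials.tsv", sep="\t", index=False)

    summary = {
        "profile": config.name,
        "seed": int(seed),
        "n_trials": int(result.aggregate["n"]),
        "correct_fraction": result.correct_fraction,
        "categories": {
            cat: {"percent": pct, "sem": sem}
            for cat, (pct, sem) in result.aggregate["categories"].items()
        },
        "first_error_positions": {
            str(k): int(v) for k, v in result.aggregate["first_error_positions"].items()
        },
        "config": {
            "buffer_network": config.buffer_network,
            "lexicon_network": config.lexicon_network,
            "coupling": config.coupling,
            "lexicon": config.lexicon,
            "protocol": config.protocol,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def read_summary(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "summary.json").read_text())


def write_trajectory(record, out_path: str | Path) -> None:
    """Delimited overlap trajectory of a single trial (t, pattern_id, overlap)."""
    if record.trajectory is None:
        raise ValueError("trial was run without keep_trajectories")
    m = record.trajectory["m_buf"]
    rows = []
    for mu in sorted({u.pattern_id for u in record.utterances} | set(record.target)):
        for t in range(m.shape[0]):
            rows.append((t, mu, float(m[t, mu])))
    df = pd.DataFrame(rows, columns=["t", "pattern_id", "overlap"])
    df.to_csv(out_path, sep="\t", index=False, float_format="%.8g")
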