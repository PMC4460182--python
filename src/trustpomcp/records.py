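"""Plain-text serialization of games and histories.

Games are written as a CSV with one row per round plus a JSON sidecar
carrying the specs, seed and search configuration that produced them,
so every output is regenerable.  Observed histories for fitting use the
same dialect restricted to the action columns; the degenerate trustee
round (zero investment) is encoded as category -1.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .agents import AgentSpec
from .game import GAME_LENGTH, N_ACTIONS
from .planner import SearchConfig
from .simulate import GameRecord

HISTORY_COLUMNS = ("round", "investor_cat", "trustee_cat")


def game_record_frame(record: GameRecord) -> pd.DataFrame:
    rows = []
    for t, (i, j) in enumerate(record.exchanges, start=1):
        chi_i, chi_t = record.payoffs[t - 1]
        bi = record.investor_posteriors[t - 1]
        bt = record.trustee_posteriors[t - 1]
        rows.append({
            "round": t,
            "investor_cat": i,
            "trustee_cat": -1 if i == 0 else j,
            "chi_investor": chi_i,
            "chi_trustee": chi_t,
            "inv_post_0": bi[0], "inv_post_0.4": bi[1], "inv_post_1": bi[2],
            "tru_post_0": bt[0], "tru_post_0.4": bt[1], "tru_post_1": bt[2],
        })
    return pd.DataFrame(rows)


def spec_to_dict(spec: AgentSpec) -> dict:
    return {"role": spec.role, "k": spec.k, "alpha": spec.alpha,
            "P": spec.P, "beta": spec.beta}


def spec_from_dict(d: dict) -> AgentSpec:
    return AgentSpec(d["role"], int(d["k"]), float(d["alpha"]), int(d["P"]),
                     float(d.get("beta", AgentSpec.__dataclass_fields__["beta"].default)))


def write_game_record(record: GameRecord, config: SearchConfig, csv_path) -> None:
    """Write the per-round CSV and a .json sidecar with full provenance."""
    csv_path = Path(csv_path)
    game_record_frame(record).to_csv(csv_path, index=False)
    sidecar = {
        "investor": spec_to_dict(record.investor),
        "trustee": spec_to_dict(record.trustee),
        "seed": record.seed,
        "config": dataclasses.asdict(config),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_history(path) -> list[tuple[int, int]]:
    """Read an observed history (list of (investor, trustee) category
    pairs) from the CSV dialect; validates category ranges per row."""
    df = pd.read_csv(path)
    missing = [c for c in HISTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"history file lacks columns {missing}")
    df = df.sort_values("round")
    history = []
    for _, row in df.iterrows():
        t, i, j = int(row["round"]), int(row["investor_cat"]), int(row["trustee_cat"])
        if not 0 <= i < N_ACTIONS:
            raise ValueError(f"row {t}: investor category {i} outside 0..4")
        if i == 0:
            if j not in (-1, 0):
                raise ValueError(f"row {t}: expected degenerate trustee round")
            j = 0
        elif not 0 <= j < N_ACTIONS:
            raise ValueError(f"row {t}: trustee category {j} outside 0..4")
        history.append((i, j))
    if len(history) > GAME_LENGTH:
        raise ValueError(f"a game has at most {GAME_LENGTH} rounds")
    return history


def write_history(history, path) -> None:
    rows = [{"round": t, "investor_cat": i, "trustee_cat": -1 if i == 0 else j}
            for t, (i, j) in enumerate(history, start=1)]
    pd.DataFrame(rows, columns=list(HISTORY_COLUMNS)).to_csv(path, index=False)
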