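import numpy as np
import pandas as pd
import pytest

from runvalue.features import FeatureConfig
from runvalue.pitch import Pitch
from runvalue.simulate import SimConfig, simulate_match
from runvalue.trackdata import TRACKING_COLUMNS, FrameTable

#: a short match for unit tests — everything but goal statistics is exercised
FAST_SIM = SimConfig(duration_s=120.0)


@pytest.fixture(scope="session")
def small_match():
    return simulate_match(FAST_SIM, seed=42, match_id="m000")


@pytest.fixture(scope="session")
def fast_feature_config():
    return FeatureConfig(pc_grid_cell=4.0)


@pytest.fixture()
def toy_pitch():
    return Pitch(attack_directions={("A", 1): 1, ("B", 1): -1})


def make_frame_table(frames, players_a=None, players_b=None, ball=None,
                     match_id="t0", fps=25.0):
    """Build a toy FrameTable from per-frame position dicts.

    ``players_a``/``players_b`` map player_id -> (x, y) or a callable
    frame -> (x, y); ``ball`` likewise.
    """
    players_a = players_a or {}
    players_b = players_b or {}
    ball = ball if ball is not None else (0.0, 0.0)
    rows = []
    for f in frames:
        bx, by = ball(f) if callable(ball) else ball
        rows.append((match_id, 1, f, f / fps, "ball", None, None, bx, by))
        for team, players in (("A", players_a), ("B", players_b)):
            for pid, p in players.items():
                x, y = p(f) if callable(p) else p
                rows.append((match_id, 1, f, f / fps, "player", team, pid, x, y))
    df = pd.DataFrame(rows, columns=TRACKING_COLUMNS)
    for c in ("match_id", "kind", "team_id", "player_id"):
        df[c] = df[c].astype("string")
    return FrameTable(df, fps=fps)
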