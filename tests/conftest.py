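import numpy as np
import pandas as pd
import pytest

import salcval as sv


@pytest.fixture(scope="session")
def two_class_sim():
    """Moderate two-taste/one-scale simulated panel reused across tests."""
    truth = sv.two_taste_truth()
    config = sv.DesignConfig(n_respondents=300)
    data_df, respondents, assignments = sv.simulate_dataset(config, truth, seed=11)
    data = sv.ChoiceData.from_frame(data_df)
    return {
        "truth": truth, "config": config, "frame": data_df,
        "respondents": respondents, "assignments": assignments, "data": data,
    }


def tiny_frame(n_resp=3, n_tasks=3, seed=0):
    """Hand-sized long-format dataset for brute-force oracles."""
    rng = np.random.default_rng(seed)
    rows = []
    states = ["11111", "21345", "53214", "45252", "33333", "12421"]
    for r in range(1, n_resp + 1):
        for t in range(n_tasks):
            ttype = ["latent_pair", "matched_AB", "matched_BC"][t % 3]
            sa, sb = rng.choice(states, size=2, replace=False)
            if ttype == "latent_pair":
                ta = tb = 1.0
            else:
                ta, tb = rng.choice([1.0, 4.0, 10.0], size=2)
            y = int(rng.random() < 0.5)
            dur = float(rng.uniform(5, 80))
            rows.append((r, f"T{t}", ttype, "A", sa, ta, dur, y))
            rows.append((r, f"T{t}", ttype, "B", sb, tb, dur, 1 - y))
    return pd.DataFrame(rows, columns=[
        "respondent_id", "task_id", "task_type", "alt_id",
        "state", "lifespan_years", "duration_sec", "chosen",
    ])


@pytest.fixture()
def tiny_data():
    return sv.ChoiceData.from_frame(tiny_frame())
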