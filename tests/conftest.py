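import numpy as np
import pandas as pd
import pytest

from mslscreen.simulate import GenomeSimConfig, ScreenSimConfig, simulate_genome, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """One 24-well plate pair with moderate noise, no spikes."""
    cfg = ScreenSimConfig(n_plates=1, wells_per_plate=24, noise_cv=0.1,
                          plate_scale_sd=0.05, seed=11)
    wells, truth = simulate_screen(cfg)
    return cfg, wells, truth


@pytest.fixture(scope="session")
def toy_genome():
    cfg = GenomeSimConfig(n_mres_per_chrom=300, reads_per_sample=20_000, seed=7)
    return cfg, simulate_genome(cfg)


def random_plate_pair(rng, n_sample=20, spikes=()):
    """Two replicate dicts amplicon -> (firefly, renilla) for oracle tests."""
    amps = [f"a{i}" for i in range(n_sample)]
    reps = []
    for _ in range(2):
        rep = {}
        for i, a in enumerate(amps):
            eff = dict(spikes).get(a, 1.0)
            f = 2000 * eff * rng.lognormal(0, 0.15)
            r = 1000 * rng.lognormal(0, 0.15)
            rep[a] = (f, r)
        reps.append(rep)
    return amps, reps[0], reps[1]


def plate_frame_from_dicts(rep1, rep2, plate_id="P001"):
    """Assemble a screen well table from two replicate dicts, adding clean
    control wells so plate QC passes."""
    rows = []
    for rep, d in ((1, rep1), (2, rep2)):
        rows.append({"plate_id": plate_id, "replicate": rep, "well": "A01",
                     "amplicon_id": "msl2_ctrl", "role": "pos_ctrl",
                     "firefly": 200.0, "renilla": 1000.0})
        rows.append({"plate_id": plate_id, "replicate": rep, "well": "A02",
                     "amplicon_id": "gfp_ctrl", "role": "neg_ctrl",
                     "firefly": 2000.0, "renilla": 1000.0})
        for i, (a, (f, r)) in enumerate(d.items()):
            rows.append({"plate_id": plate_id, "replicate": rep,
                         "well": f"B{i + 1:02d}", "amplicon_id": a,
                         "role": "sample", "firefly": f, "renilla": r})
    return pd.DataFrame(rows)


def random_intervals(rng, n, chroms=("X", "2L"), max_pos=10_000, max_len=300):
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame({
        "chrom": rng.choice(chroms, size=n),
        "start": starts,
        "end": starts + lengths,
        "name": [f"iv{i}" for i in range(n)],
    })
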