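import pandas as pd
import pytest

from pislice.pipeline import RunConfig, run_all
from pislice.simulate import SimConfig, generate_world

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic study (seed 1)."""
    return generate_world(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_report(default_world):
    """Full pipeline report on the default synthetic study."""
    return run_all(RunConfig(), world=default_world)


@pytest.fixture(scope="session")
def small_world():
    """A reduced world for exhaustive (brute-force) comparisons."""
    return generate_world(SimConfig(
        seed=7, n_transcripts=24, transcript_length_range=(600, 1200),
        depth=200_000, degradome_depth=2_000_000, smallrna_depth=500_000,
    ))


def brute_force_calls(guides: pd.DataFrame, transcripts: dict[str, str]) -> set:
    """Independent exhaustive scorer: enumerate every window of every
    transcript for every guide and apply the four tier rules, hand-coded
    with plain string comparisons."""
    calls = set()
    for t_id, seq in transcripts.items():
        n = len(seq)
        for p in range(n):
            for row in guides.itertuples():
                g = row.sequence
                m = []
                for k in range(1, 31):
                    t = p + 10 - k
                    ok = (k <= len(g) and 0 <= t < n
                          and seq[t] == COMPLEMENT[g[k - 1]])
                    m.append(ok)
                hit = False
                if row.ppm >= 1 and sum(m[1:25]) >= 20:
                    hit = True
                if row.ppm >= 5 and all(m[2:15]):
                    hit = True
                if row.ppm >= 10 and all(m[2:16]):
                    hit = True
                if row.ppm >= 50 and all(m[3:17]):
                    hit = True
                if hit:
                    calls.add((row.guide_id, t_id, p))
    return calls
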