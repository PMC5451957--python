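"""Seed plumbing: one master seed deterministically derives per-stage seeds."""

from __future__ import annotations

import numpy as np

# Fixed ordering of pipeline stages; index feeds the SeedSequence spawn key.
STAGE_ORDER = (
    "simulate",
    "build-exposure",
    "fit-bpr",
    "fit-bpr-no-outcome",
    "characterize",
    "fit-bkmr",
    "spatial",
    "report",
)


def derive_seed(master_seed: int, stage: str | int) -> int:
    """Derive a stage seed (< 2**31) from the master seed.

    Deterministic and collision-resistant via numpy's SeedSequence; the same
    (master_seed, stage) pair always yields the same stage seed.
    """
    idx = STAGE_ORDER.index(stage) if isinstance(stage, str) else int(stage)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
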