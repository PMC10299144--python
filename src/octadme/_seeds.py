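"""Per-stage sub-seed derivation.

Each pipeline stage draws its randomness from a sub-seed derived from the
global seed and the stage name, so enabling or disabling one stage never
shifts another stage's stream, and replicate k of an experiment is stable
regardless of how many replicates run.
"""

from __future__ import annotations

import zlib


def stage_seed(global_seed: int, stage: str, replicate: int = 0) -> int:
    """Deterministic sub-seed < 2**31 for (global seed, stage, replicate)."""
    h = zlib.crc32(f"{stage}:{replicate}".encode())
    return (int(global_seed) * 1_000_003 + h) % (2**31)
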