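"""Shared helpers: seed fan-out, rank utilities, small validation tools."""

from __future__ import annotations

import numpy as np

# Stage names used by the pipeline seed splitter. Keeping the list explicit
# (rather than hashing names) makes the fan-out stable across releases.
_STAGE_ORDER = (
    "synthetic",
    "normative",
    "factors_pos",
    "factors_neg",
    "significance_pos",
    "significance_neg",
    "robustness_pos",
    "robustness_neg",
    "transfer",
    "bridge",
    "clinical",
    "annotation",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage integer seed (< 2**31) from one global seed.

    Uses :class:`numpy.random.SeedSequence` spawning so stages can be rerun
    in isolation and still reproduce the pipeline run.
    """
    if stage not in _STAGE_ORDER:
        raise KeyError(f"unknown stage {stage!r}")
    idx = _STAGE_ORDER.index(stage)
    child = np.random.SeedSequence(global_seed).spawn(len(_STAGE_ORDER))[idx]
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


def as_2d(x: np.ndarray, name: str = "array") -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {x.shape}")
    return x


def check_finite(x: np.ndarray, name: str = "array") -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in {name}")
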