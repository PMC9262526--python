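"""Small shared helpers: report rounding and named RNG substreams."""

from __future__ import annotations

import zlib

import numpy as np

# Elements and QoL domains, in canonical order. Every 6-vector / 8-vector in
# the package follows these orderings.
ELEMENTS = (
    "liver",
    "stomach",
    "heat",
    "spleen_dampness",
    "qi_deficiency",
    "qi_stagnation",
)
DOMAINS = (
    "activity",
    "anxiety",
    "diet",
    "sleep",
    "discomfort",
    "health_perceptions",
    "coping",
    "stress",
)
TOTAL = "total"
N_ELEMENTS = len(ELEMENTS)
N_DOMAINS = len(DOMAINS)


def round_half_away(x, ndigits: int = 4):
    """Round half away from zero (report convention; numpy rounds half to even)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from a master seed and a label.

    Stages of the pipeline each draw from their own named stream so any stage
    can be re-run in isolation with identical randomness.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))
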