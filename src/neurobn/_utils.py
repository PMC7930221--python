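"""Shared helpers: named seed substreams and z-standardization."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd


def substream_seed(master_seed: int, *names: object) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed and a name path.

    Named derivation (rather than sequential spawning) means adding a new
    consumer never perturbs the streams of existing ones.
    """
    key = ":".join([str(int(master_seed))] + [str(n) for n in names])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize columns (mean 0, SD 1; SD with denominator N-1).

    Raises ``ValueError`` naming the offending column if one is constant.
    """
    sd = data.std(ddof=1)
    bad = sd.index[(sd == 0) | sd.isna()].tolist()
    if bad:
        raise ValueError(f"constant or degenerate column(s): {bad}")
    return (data - data.mean()) / sd
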