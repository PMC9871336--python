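"""Access to the packaged reference datasets.

One JSON file ships with the package: published measurement summaries for
the KIF1A loop-12 construct series (dwell/run-length pairs, the loop-12
charge ledger, charge vs run-length points per buffer, buffer constants,
and pelleting/on-rate constants). These are inputs for worked examples and
consistency validation, not computed outputs.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Any

import pandas as pd

__all__ = [
    "reference_data",
    "table1_frame",
    "loop12_ledger",
    "charge_run_length_points",
]


@lru_cache(maxsize=1)
def reference_data() -> dict[str, Any]:
    """The raw packaged reference dictionary (cached)."""
    with resources.files("kinrace.data").joinpath("reference_data.json").open() as fh:
        return json.load(fh)


def table1_frame() -> pd.DataFrame:
    """Per-construct (dwell, run length) measurements as a DataFrame."""
    return pd.DataFrame(reference_data()["table1"])


def loop12_ledger() -> list[dict[str, Any]]:
    """Loop-12 charge ledger entries (construct, lysine_count, net_charge, parent)."""
    return [dict(e) for e in reference_data()["loop12_ledger"]]


def charge_run_length_points(buffer: str) -> pd.DataFrame:
    """(net charge, run length) points for one buffer; N.D. rows retained as NaN."""
    data = reference_data()["charge_run_length"]
    if buffer not in data:
        raise KeyError(f"unknown buffer {buffer!r}; have {sorted(data)}")
    return pd.DataFrame(data[buffer])
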