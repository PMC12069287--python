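"""Bundled fixture tables and design-matrix builders.

The eight fixture tables carry the published laboratory and calibration
numbers used as references throughout the toolkit (see
``fixtures/NOTES.md`` for provenance and the printed anomalies, which are
preserved verbatim, never silently corrected).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .doe import CCD_FACTORS, PB_FACTORS, DesignMatrix

__all__ = ["fixture", "available_fixtures", "table4_design", "table6_design",
           "COMPRESSION_TARGET_N"]

#: mean laboratory peak compression force, N — the calibration target.
COMPRESSION_TARGET_N = 1553.51

_FIXTURES = {f"table{i}": f"table{i}.csv" for i in range(1, 9)}


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def fixture(name: str) -> pd.DataFrame:
    """Load a bundled fixture table by name (``table1`` … ``table8``)."""
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        )
    ref = resources.files("stemdem.fixtures").joinpath(_FIXTURES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def table4_design() -> DesignMatrix:
    """The 21-run Plackett–Burman screening design with its responses."""
    df = fixture("table4")
    runs = df[[f.name for f in PB_FACTORS]].to_numpy(float)
    return DesignMatrix(list(PB_FACTORS), runs, df["F_max"].to_numpy(float))


def table6_design() -> DesignMatrix:
    """The 27-run face-centred CCD with its mean responses."""
    df = fixture("table6")
    runs = df[[f.name for f in CCD_FACTORS]].to_numpy(float)
    return DesignMatrix(list(CCD_FACTORS), runs, df["F_max"].to_numpy(float))
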