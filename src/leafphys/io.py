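"""Reading and writing analysis tables.

All tables are CSV; output files carry a small metadata header of comment
lines (``# key: value``) recording at least the package version and the seed,
which pandas skips transparently on read (``comment='#'``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_table", "read_table", "read_curves"]


def write_table(df: pd.DataFrame, path: str | Path,
                metadata: dict | None = None) -> None:
    """Write a CSV with a ``# key: value`` metadata header block."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"leafphys_version": __version__}
    meta.update(metadata or {})
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (metadata lines skipped)."""
    return pd.read_csv(path, comment="#")


def read_curves(path: str | Path) -> pd.DataFrame:
    """Read a curve dataset CSV, validating the schema columns."""
    from .synthetic_data import CURVE_COLUMNS

    df = pd.read_csv(path, comment="#")
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curve dataset missing columns: {sorted(missing)}")
    return df
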