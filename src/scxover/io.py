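"""Bit-stable CSV I/O with provenance header comments."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "none",
                float_format: str | None = None) -> None:
    """Write a CSV with a `# scxover <version> config=<hash>` header comment.

    Machine files keep full float precision; report files pass
    ``float_format="%.3f"`` for 3-decimal presentation.
    """
    from . import __version__

    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# scxover {__version__} config={config_hash}\n")
        df.to_csv(fh, index=False, float_format=float_format, lineterminator="\n")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a CSV written by ``write_table`` (header comments skipped)."""
    return pd.read_csv(path, comment="#", **kwargs)
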