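"""TSV helpers: all tabular outputs use a single header line starting with '#'."""

from __future__ import annotations

import io

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write ``df`` as TSV with a '#'-prefixed header line (deterministic)."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format=FLOAT_FORMAT)
    text = buf.getvalue()
    with open(path, "w") as fh:
        if text:
            head, _, rest = text.partition("\n")
            fh.write("#" + head + "\n" + rest)


def read_tsv(path) -> pd.DataFrame:
    """Read a TSV whose first line is a '#'-prefixed header."""
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return pd.DataFrame()
        names = header.lstrip("#").rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", names=names, header=None)
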