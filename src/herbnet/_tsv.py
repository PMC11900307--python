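"""Shared tab-separated-value reading helpers.

Dialect: tab-delimited, ``#``-prefixed comment lines skipped, blank lines
skipped, and the first row treated as a header iff its first cell matches a
configured header-name set (the reference interactome distribution ships
headered TSVs such as ``node_1 / node_2``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

# header cells seen in the supported table dialects (lowercased)
DEFAULT_HEADER_NAMES = frozenset({
    "node_1", "node_2", "herb", "compound", "component", "gene", "target",
    "protein", "function", "entrez", "pubchem_cid", "source",
    "association_type", "log2fc", "padj", "score", "child", "parent",
})


class TSVFormatError(ValueError):
    """Malformed row in a tab-separated input file."""


def iter_tsv_rows(
    path: str | Path,
    min_columns: int,
    header_names: frozenset[str] = DEFAULT_HEADER_NAMES,
) -> Iterator[tuple[int, list[str]]]:
    """Yield ``(line_number, cells)`` for each data row.

    Cells are whitespace-trimmed. A row with fewer than ``min_columns``
    non-empty leading cells raises :class:`TSVFormatError` with its line
    number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    first_data_row = True
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = [c.strip() for c in line.split("\t")]
            if first_data_row:
                first_data_row = False
                if cells and cells[0].lower() in header_names:
                    continue
            if len(cells) < min_columns or any(not c for c in cells[:min_columns]):
                raise TSVFormatError(
                    f"{path}:{lineno}: expected at least {min_columns} "
                    f"non-empty tab-separated fields, got {line!r}"
                )
            yield lineno, cells
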