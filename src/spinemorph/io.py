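"""CSV reading and writing for morphometry tables.

The interchange dialect is fixed: comma-separated, UTF-8, "." decimal
separator, mandatory header row, enum tokens in lower-case snake-case and the
``branched`` flag serialised as ``true``/``false``. Floats are written with
full round-trip precision so ``read(write(D)) == D`` exactly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datamodel import Dataset, SchemaError, empty_table, validate_table

TABLE_FILES = {"spines": "spines.csv", "segments": "segments.csv", "somata": "somata.csv"}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one CSV table of the given schema.

    Returns a typed DataFrame; raises :class:`SchemaError` or
    :class:`ValidationError` with row-indexed diagnostics on malformed input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected a header row") from exc
    return validate_table(raw, schema)


def read_dataset(directory: str | Path, provenance: str | None = None) -> Dataset:
    """Load whichever of spines/segments/somata CSVs exist under *directory*."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"data directory not found: {directory}")
    tables = {}
    for schema, fname in TABLE_FILES.items():
        path = directory / fname
        tables[schema] = read_table(path, schema) if path.exists() else empty_table(schema)
    ds = Dataset(
        spines=tables["spines"],
        segments=tables["segments"],
        somata=tables["somata"],
        provenance=provenance or f"loaded from {directory}",
    )
    return ds.validate()


def write_tables(dataset: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset as one CSV per record kind; returns written paths.

    Empty tables are written as header-only files so a directory always
    contains the full trio.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for schema, fname in TABLE_FILES.items():
        df = getattr(dataset, schema).copy()
        if "branched" in df.columns:
            df["branched"] = df["branched"].map({True: "true", False: "false"})
        path = directory / fname
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(path, index=False, float_format="%.17g")
        paths[schema] = path
    return paths
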