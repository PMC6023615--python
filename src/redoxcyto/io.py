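"""Readers and writers for the pipeline's table formats.

Event tables come in as FCS 3.0/3.1 or delimited text with a configurable
channel-name mapping; everything else (growth curves, trajectories,
phenotypes, abundance matrices, summaries) travels as TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .fcs import read_fcs, write_fcs
from .cytometry import MissingChannelError

__all__ = [
    "DEFAULT_CHANNEL_MAP",
    "read_events",
    "write_events",
    "read_abundance_tsv",
    "write_abundance_tsv",
]

#: logical channel -> on-disk channel name used when writing FCS
DEFAULT_CHANNEL_MAP: dict[str, str] = {
    "i405": "VL1-405",
    "i488": "BL1-488",
    "pi": "PI",
    "marker": "MARKER",
}


def read_events(
    path: str | Path, channel_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read an event table from FCS or delimited text.

    ``channel_map`` maps logical names (``i405``, ``i488``, ``pi``,
    ``marker``) to the file's channel/column names; the default matches the
    names this package writes.  Logical channels absent from the mapping are
    simply not required; mapped channels missing from the file raise
    :class:`~redoxcyto.cytometry.MissingChannelError` naming the channel.
    """
    path = Path(path)
    cmap = DEFAULT_CHANNEL_MAP if channel_map is None else channel_map
    if path.suffix.lower() == ".fcs":
        raw = read_fcs(path)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        raw = pd.read_csv(path, sep=sep)
    out = pd.DataFrame(index=raw.index)
    for logical, source in cmap.items():
        if source in raw.columns:
            out[logical] = raw[source]
        elif logical in raw.columns:  # already logical names
            out[logical] = raw[logical]
        elif logical in ("i405", "i488", "pi"):
            raise MissingChannelError(
                f"{path.name}: mapped channel {source!r} (logical {logical!r}) not found; "
                f"available: {list(raw.columns)}"
            )
    for extra in ("truth_state",):
        if extra in raw.columns:
            out[extra] = raw[extra]
    out.attrs.update({"path": str(path), "n_events": len(out), "channels": list(out.columns)})
    return out


def write_events(
    events: pd.DataFrame,
    path: str | Path,
    *,
    channel_map: dict[str, str] | None = None,
) -> None:
    """Write an event table as FCS 3.1 (``.fcs``) or TSV (anything else)."""
    path = Path(path)
    cmap = DEFAULT_CHANNEL_MAP if channel_map is None else channel_map
    numeric = events.select_dtypes("number")
    if path.suffix.lower() == ".fcs":
        renamed = numeric.rename(columns={k: v for k, v in cmap.items() if k in numeric})
        write_fcs(renamed, path)
    else:
        events.to_csv(path, sep="\t", index=False)


def read_abundance_tsv(values_path: str | Path, samples_path: str | Path, modality: str):
    """Load an abundance matrix (features x samples TSV) plus sample sheet."""
    from .omics import AbundanceMatrix

    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return AbundanceMatrix(values=values, samples=samples, modality=modality)


def write_abundance_tsv(matrix, values_path: str | Path, samples_path: str | Path) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    matrix.samples.to_csv(samples_path, sep="\t")
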