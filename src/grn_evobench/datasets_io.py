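"""Reading and writing expression time-series tables and regulatory model files.

Time series travel as delimited text (comma or tab, auto-detected): a header
row ``time,<gene1>,<gene2>,...`` followed by numeric rows. A dataset holding
several independent series (e.g. several perturbation experiments on the same
genes) is encoded as blocks separated by lines starting with ``# series``;
a file without separators is a single series.

Ground-truth and inferred models are exchanged as JSON with an explicit
``model_type`` tag (``"ssystem"`` or ``"ann"``) so that benchmark drivers can
load either family without prior knowledge.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np

from .ssystem import SSystemModel
from .ann_model import AnnGeneModel, AnnNetworkModel

__all__ = [
    "ExpressionDataset",
    "TimeSeriesParseError",
    "read_timeseries",
    "write_timeseries",
    "read_model",
    "write_model",
]


class TimeSeriesParseError(ValueError):
    """Raised when a time-series table violates the format contract."""


@dataclasses.dataclass
class ExpressionDataset:
    """One or more gene-expression time series over a common gene set.

    Parameters
    ----------
    series
        List of ``(times, values)`` pairs. ``times`` is a strictly increasing
        1-D float array; ``values`` is a ``len(times) x n_genes`` float array
        of non-negative expression levels.
    gene_names
        Ordered gene identifiers; every series' value matrix has exactly
        ``len(gene_names)`` columns.
    """

    series: list[tuple[np.ndarray, np.ndarray]]
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.gene_names = list(self.gene_names)
        clean = []
        for k, (t, x) in enumerate(self.series):
            t = np.asarray(t, dtype=float)
            x = np.asarray(x, dtype=float)
            if t.ndim != 1 or x.ndim != 2 or x.shape[0] != t.shape[0]:
                raise ValueError(f"series {k}: times/values shapes inconsistent")
            if x.shape[1] != len(self.gene_names):
                raise ValueError(
                    f"series {k}: {x.shape[1]} columns for "
                    f"{len(self.gene_names)} gene names"
                )
            if not np.all(np.isfinite(t)) or not np.all(np.isfinite(x)):
                raise ValueError(f"series {k}: non-finite entries")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"series {k}: times not strictly increasing")
            clean.append((t, x))
        self.series = clean

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_points(self) -> int:
        """Total number of time points across all series."""
        return sum(t.size for t, _ in self.series)

    def values_concat(self) -> np.ndarray:
        """All expression values stacked (sum of series lengths) x n_genes."""
        return np.concatenate([x for _, x in self.series], axis=0)


def read_timeseries(path: Union[str, Path], delimiter: str | None = None) -> ExpressionDataset:
    """Parse a delimited time-series table into an :class:`ExpressionDataset`.

    The first header row names the genes (first column is time). Blocks
    separated by ``# series`` lines become separate series sharing the header.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.rstrip("\n") for ln in text.splitlines()]
    if delimiter is None:
        first_data = next((ln for ln in lines if ln.strip() and not ln.startswith("#")), "")
        delimiter = "\t" if "\t" in first_data else ","

    header: list[str] | None = None
    blocks: list[list[tuple[int, str]]] = [[]]
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        if ln.lstrip().startswith("#"):
            if "series" in ln.lower() and blocks[-1]:
                blocks.append([])
            continue
        if header is None:
            header = [c.strip() for c in ln.split(delimiter)]
            continue
        blocks[-1].append((lineno, ln))

    if header is None or len(header) < 2:
        raise TimeSeriesParseError(f"{path}: missing or too-short header row")
    gene_names = header[1:]

    series = []
    for block in blocks:
        if not block:
            continue
        times, rows = [], []
        for lineno, ln in block:
            cells = [c.strip() for c in ln.split(delimiter)]
            if len(cells) != len(header):
                raise TimeSeriesParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            parsed = []
            for col, cell in enumerate(cells):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise TimeSeriesParseError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column "
                        f"{header[col]!r}"
                    ) from None
            if not all(np.isfinite(parsed)):
                raise TimeSeriesParseError(f"{path}:{lineno}: non-finite value")
            times.append(parsed[0])
            rows.append(parsed[1:])
        t = np.array(times)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise TimeSeriesParseError(f"{path}: time stamps not strictly increasing")
        series.append((t, np.array(rows)))
    if not series:
        raise TimeSeriesParseError(f"{path}: no data rows")
    return ExpressionDataset(series=series, gene_names=gene_names)


def write_timeseries(dataset: ExpressionDataset, path: Union[str, Path], delimiter: str = ",") -> None:
    """Write a dataset so that :func:`read_timeseries` reproduces it exactly.

    Values are printed with ``repr``-level precision, so a read/write
    roundtrip is the identity on the parsed floats.
    """
    path = Path(path)
    out = [delimiter.join(["time"] + list(dataset.gene_names))]
    for k, (t, x) in enumerate(dataset.series):
        if len(dataset.series) > 1:
            out.append(f"# series {k}")
        for i in range(t.size):
            row = [np.format_float_positional(t[i], trim="0", precision=None)]
            row += [np.format_float_positional(v, trim="0", precision=None) for v in x[i]]
            out.append(delimiter.join(row))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Model files


def _model_to_dict(model) -> dict:
    if isinstance(model, SSystemModel):
        return {
            "model_type": "ssystem",
            "alpha": model.alpha.tolist(),
            "beta": model.beta.tolist(),
            "g": model.g.tolist(),
            "h": model.h.tolist(),
        }
    if isinstance(model, AnnNetworkModel):
        return {
            "model_type": "ann",
            "gene_names": list(model.gene_names),
            "genes": [
                {
                    "gene_index": gm.gene_index,
                    "regulators": list(gm.regulators),
                    "weights": list(np.asarray(gm.weights, dtype=float)),
                    "bias": float(gm.bias),
                    "scale_min": float(gm.scale_min),
                    "scale_max": float(gm.scale_max),
                }
                for gm in model.genes
            ],
        }
    raise TypeError(f"unsupported model object {type(model).__name__}")


def _model_from_dict(d: dict):
    mtype = d.get("model_type")
    if mtype == "ssystem":
        return SSystemModel(
            alpha=np.array(d["alpha"], dtype=float),
            beta=np.array(d["beta"], dtype=float),
            g=np.array(d["g"], dtype=float),
            h=np.array(d["h"], dtype=float),
        )
    if mtype == "ann":
        genes = [
            AnnGeneModel(
                gene_index=int(g["gene_index"]),
                regulators=tuple(int(r) for r in g["regulators"]),
                weights=np.array(g["weights"], dtype=float),
                bias=float(g["bias"]),
                scale_min=float(g["scale_min"]),
                scale_max=float(g["scale_max"]),
            )
            for g in d["genes"]
        ]
        return AnnNetworkModel(genes=genes, gene_names=list(d["gene_names"]))
    raise ValueError(f"unknown model_type {mtype!r}")


def write_model(model, path: Union[str, Path]) -> None:
    """Serialise an S-System or ANN network model to a tagged JSON file."""
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1) + "\n")


def read_model(path: Union[str, Path]):
    """Load a model JSON file; returns :class:`~grn_evobench.ssystem.SSystemModel`
    or :class:`~grn_evobench.ann_model.AnnNetworkModel` depending on its tag."""
    with open(path) as fh:
        return _model_from_dict(json.load(fh))
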