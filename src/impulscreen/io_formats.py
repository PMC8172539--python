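"""Readers and writers for every external representation the pipeline touches.

Expression matrices travel as Matrix Market coordinate files (or dense CSV)
with one-symbol-per-line gene/cell index files; annotations as CSV/TSV tables
with headers; operant session logs as a minimal CSV dialect (``time_s, event,
arg``); screen results as TSV reports.  Matrix orientation is fixed:
genes in rows, cells in columns — every entry point states and validates this.

All writers emit a leading comment line recording the tool version and, when
supplied, a configuration hash, so that the files of one run can be checked
for provenance consistency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

__all__ = [
    "ExpressionDataset",
    "SessionLog",
    "CELL_CLASSES",
    "COUPLING_CLASSES",
    "EVENT_KINDS",
    "HOLE_EVENTS",
    "read_expression",
    "write_expression",
    "read_annotations",
    "read_session_log",
    "write_session_log",
    "write_screen_report",
    "read_screen_report",
]

logger = logging.getLogger(__name__)

#: Closed vocabulary for the transcriptomic cell classes.
CELL_CLASSES = ("glutamatergic", "GABAergic", "non-neuronal")

#: Closed vocabulary for G-protein coupling of a receptor.
COUPLING_CLASSES = ("Gi", "Gq", "Gs", "other", "unknown")

#: Legal operant-box event kinds.
EVENT_KINDS = (
    "poke_in",
    "poke_out",
    "receptacle_in",
    "receptacle_out",
    "stim_on",
    "stim_off",
    "reward",
    "timeout_start",
    "timeout_end",
    "session_end",
)

#: Events whose ``arg`` column must carry a 5-choice hole index (1-5).
HOLE_EVENTS = frozenset({"poke_in", "poke_out", "stim_on", "stim_off"})

#: Timestamps may jitter backwards by at most this much (seconds) and still
#: be merged by a stable re-sort; anything larger is a validation error.
TIME_TOLERANCE_S = 1e-3


def _tool_comment(config_hash: str | None = None) -> str:
    from . import __version__

    tag = f"impulscreen v{__version__}"
    if config_hash:
        tag += f" config={config_hash}"
    return tag


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A genes x cells matrix of CPM values with its axis labels.

    The matrix holds counts-per-million normalised expression (exons+introns
    scale); zeros are stored implicitly (CSR).  Gene symbols index the rows,
    cell identifiers the columns, both unique and order-preserving.
    """

    matrix: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.matrix.shape[0] != len(self.gene_ids):
            raise FormatError(
                f"gene axis mismatch: matrix has {self.matrix.shape[0]} rows "
                f"but {len(self.gene_ids)} gene ids were supplied"
            )
        if self.matrix.shape[1] != len(self.cell_ids):
            raise FormatError(
                f"cell axis mismatch: matrix has {self.matrix.shape[1]} columns "
                f"but {len(self.cell_ids)} cell ids were supplied"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dup = pd.Index(ids).duplicated()
            if dup.any():
                offenders = sorted(set(np.asarray(ids)[dup]))
                raise ValidationError(f"duplicate {name} ids: {offenders[:10]}")
        data = self.matrix.data
        bad = ~np.isfinite(data) | (data < 0)
        if bad.any():
            coo = self.matrix.tocoo()
            mask = ~np.isfinite(coo.data) | (coo.data < 0)
            g = self.gene_ids[coo.row[mask][0]]
            c = self.cell_ids[coo.col[mask][0]]
            raise ValidationError(
                f"negative or non-finite CPM value at gene {g!r}, cell {c!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def cell_positions(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Column positions of the given cell ids (error on unknown ids)."""
        idx = pd.Index(self.cell_ids)
        pos = idx.get_indexer(list(cell_ids))
        if (pos < 0).any():
            missing = [c for c, p in zip(cell_ids, pos) if p < 0]
            raise ValidationError(f"cells not present in dataset: {missing[:10]}")
        return pos

    def dense_submatrix(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Dense genes x |cells| CPM block for the given cells."""
        return np.asarray(self.matrix[:, self.cell_positions(cell_ids)].todense())


def _read_index_file(path: Path, axis: str) -> np.ndarray:
    lines = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("%", "#")):
                continue
            # tolerate a single-column CSV with a header named after the axis
            lines.append(line)
    if lines and lines[0].lower() in {axis, f"{axis}_id", f"{axis}s", "id", "symbol"}:
        lines = lines[1:]
    return np.asarray(lines, dtype=object)


def read_expression(matrix_path, genes_path, cells_path) -> ExpressionDataset:
    """Load an expression dataset from disk.

    ``matrix_path`` may be Matrix Market coordinate format (``.mtx``) or a
    dense CSV of numbers; either way rows are genes and columns are cells.
    Index files carry one identifier per line (an optional single header line
    is tolerated).
    """
    matrix_path = Path(matrix_path)
    genes = _read_index_file(Path(genes_path), "gene")
    cells = _read_index_file(Path(cells_path), "cell")
    if matrix_path.suffix.lower() in {".mtx", ".mm"}:
        try:
            mat = scipy.io.mmread(str(matrix_path))
        except Exception as exc:  # pragma: no cover - scipy message passthrough
            raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}")
        mat = sp.csr_matrix(mat)
    else:
        try:
            frame = pd.read_csv(matrix_path, header=None, comment="%")
        except Exception as exc:
            raise FormatError(f"cannot parse dense CSV matrix {matrix_path}: {exc}")
        mat = sp.csr_matrix(frame.to_numpy(dtype=np.float64))
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"gene axis mismatch: matrix {matrix_path.name} has {mat.shape[0]} "
            f"rows but gene index file lists {len(genes)} entries"
        )
    if mat.shape[1] != len(cells):
        raise FormatError(
            f"cell axis mismatch: matrix {matrix_path.name} has {mat.shape[1]} "
            f"columns but cell index file lists {len(cells)} entries"
        )
    return ExpressionDataset(mat, genes, cells)


def write_expression(
    ds: ExpressionDataset,
    matrix_path,
    genes_path,
    cells_path,
    config_hash: str | None = None,
) -> None:
    """Write a dataset as MTX + index files (inverse of :func:`read_expression`)."""
    scipy.io.mmwrite(
        str(matrix_path),
        ds.matrix.tocoo(),
        comment=_tool_comment(config_hash) + " | rows=genes cols=cells",
    )
    for path, ids in ((genes_path, ds.gene_ids), (cells_path, ds.cell_ids)):
        with open(path, "w") as fh:
            fh.write(f"% {_tool_comment(config_hash)}\n")
            for i in ids:
                fh.write(f"{i}\n")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

_CLASS_ALIASES = {c.lower(): c for c in CELL_CLASSES}
_CLASS_ALIASES.update({"non_neuronal": "non-neuronal", "nonneuronal": "non-neuronal"})

#: Default map from free-text coupling annotations to the closed vocabulary.
DEFAULT_COUPLING_ALIASES: Mapping[str, str] = {
    "gi": "Gi",
    "gi/go": "Gi",
    "gi/o": "Gi",
    "gq": "Gq",
    "gq/g11": "Gq",
    "gq/11": "Gq",
    "gs": "Gs",
    "other": "other",
    "unknown": "unknown",
}

_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n", ""}


def _parse_bool_column(col: pd.Series, name: str, path) -> pd.Series:
    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY or s == "nan":
            return False
        raise FormatError(f"{path}: cannot interpret {v!r} as boolean in column {name}")

    return col.map(one)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        return pd.read_csv(path, sep=sep, comment="#", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse table {path}: {exc}")


def read_annotations(
    cells_path,
    genes_path,
    coupling_aliases: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the cell and gene annotation tables.

    Returns ``(cell_annotation, gene_annotation)``:

    * cell table, indexed by ``cell_id``, columns ``cell_class`` (normalised to
      the closed vocabulary), ``cluster``, ``reporter_positive``, ``region``;
    * gene table, indexed by ``gene``, columns ``is_gpcr``, ``coupling``
      (closed vocabulary, free-text values resolved through the alias map and
      otherwise demoted to ``"unknown"`` with a logged warning), ``is_sensory``.
    """
    aliases = dict(DEFAULT_COUPLING_ALIASES)
    if coupling_aliases:
        aliases.update({k.lower(): v for k, v in coupling_aliases.items()})

    cells = _read_table(cells_path)
    required = ["cell_id", "cell_class", "cluster", "reporter_positive"]
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise FormatError(f"{cells_path}: missing required cell columns {missing}")
    if "region" not in cells.columns:
        cells["region"] = ""

    def norm_class(v: str) -> str:
        key = str(v).strip().lower()
        if key not in _CLASS_ALIASES:
            raise ValidationError(
                f"{cells_path}: cell class {v!r} not in {CELL_CLASSES}"
            )
        return _CLASS_ALIASES[key]

    cells = cells.copy()
    cells["cell_class"] = cells["cell_class"].map(norm_class)
    cells["reporter_positive"] = _parse_bool_column(
        cells["reporter_positive"], "reporter_positive", cells_path
    )
    dup = cells["cell_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{cells_path}: duplicated cell ids {sorted(set(cells['cell_id'][dup]))[:10]}"
        )
    cells = cells.set_index("cell_id")[
        ["cell_class", "cluster", "reporter_positive", "region"]
    ]

    genes = _read_table(genes_path)
    required = ["gene", "is_gpcr"]
    missing = [c for c in required if c not in genes.columns]
    if missing:
        raise FormatError(f"{genes_path}: missing required gene columns {missing}")
    genes = genes.copy()
    genes["is_gpcr"] = _parse_bool_column(genes["is_gpcr"], "is_gpcr", genes_path)
    if "coupling" not in genes.columns:
        genes["coupling"] = "unknown"
    if "is_sensory" not in genes.columns:
        genes["is_sensory"] = False
    else:
        genes["is_sensory"] = _parse_bool_column(
            genes["is_sensory"], "is_sensory", genes_path
        )

    def norm_coupling(v) -> str:
        s = str(v).strip()
        if s in COUPLING_CLASSES:
            return s
        mapped = aliases.get(s.lower())
        if mapped is None:
            logger.warning("unknown coupling value %r mapped to 'unknown'", v)
            return "unknown"
        return mapped

    genes["coupling"] = genes["coupling"].map(norm_coupling)
    dup = genes["gene"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{genes_path}: duplicated gene symbols {sorted(set(genes['gene'][dup]))[:10]}"
        )
    genes = genes.set_index("gene")[["is_gpcr", "coupling", "is_sensory"]]
    return cells, genes


def validate_annotation_coverage(ds: ExpressionDataset, cells: pd.DataFrame) -> None:
    """Every cell in the matrix must have exactly one annotation row."""
    missing = [c for c in ds.cell_ids if c not in cells.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} cells in matrix lack annotation rows: {missing[:10]}"
        )


def write_annotations(
    cells: pd.DataFrame, genes: pd.DataFrame, cells_path, genes_path,
    config_hash: str | None = None,
) -> None:
    for frame, path, index_label in (
        (cells, cells_path, "cell_id"),
        (genes, genes_path, "gene"),
    ):
        with open(path, "w") as fh:
            fh.write(f"# {_tool_comment(config_hash)}\n")
            frame.to_csv(fh, index_label=index_label)


# ---------------------------------------------------------------------------
# Session logs
# ---------------------------------------------------------------------------


@dataclass
class SessionLog:
    """An ordered, timestamped record of operant-box events.

    ``events`` has columns ``time_s`` (float seconds from session start),
    ``event`` (one of :data:`EVENT_KINDS`) and ``arg`` (hole index 1-5 for
    hole events, NaN otherwise).
    """

    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["time_s", "event", "arg"])
    )

    def __post_init__(self) -> None:
        ev = self.events.reset_index(drop=True)
        ev["time_s"] = ev["time_s"].astype(float)
        ev["arg"] = pd.array(ev["arg"], dtype="Int64") if len(ev) else pd.array(
            [], dtype="Int64"
        )
        self.events = ev
        self.validate()

    def __len__(self) -> int:
        return len(self.events)

    def itertuples(self):
        return self.events.itertuples(index=True)

    def validate(self) -> None:
        ev = self.events
        unknown = set(ev["event"]) - set(EVENT_KINDS)
        if unknown:
            raise FormatError(f"unknown event kinds {sorted(unknown)}")
        t = ev["time_s"].to_numpy()
        if len(t) and np.diff(t).min(initial=0.0) < -TIME_TOLERANCE_S:
            i = int(np.argmin(np.diff(t))) + 1
            raise ValidationError(
                f"timestamps decrease by more than {TIME_TOLERANCE_S*1e3:.0f} ms "
                f"at event {i} (t={t[i]:.4f} after t={t[i-1]:.4f})"
            )
        is_hole = ev["event"].isin(HOLE_EVENTS)
        if is_hole.any():
            args = ev.loc[is_hole, "arg"]
            if args.isna().any():
                i = int(args.index[args.isna()][0])
                raise FormatError(
                    f"event {ev.loc[i, 'event']!r} at row {i} requires a hole index"
                )
            bad = ~args.dropna().between(1, 5)
            if bad.any():
                raise ValidationError("hole index outside 1-5")
        if (~is_hole & ev["arg"].notna()).any():
            i = int(ev.index[(~is_hole) & ev["arg"].notna()][0])
            raise FormatError(
                f"event {ev.loc[i, 'event']!r} at row {i} must not carry a hole index"
            )
        # poke_out must close a previously opened poke on the same hole
        open_holes: set[int] = set()
        for row in ev.itertuples():
            if row.event == "poke_in":
                open_holes.add(int(row.arg))
            elif row.event == "poke_out":
                if int(row.arg) not in open_holes:
                    raise ValidationError(
                        f"poke_out at row {row.Index} without matching poke_in"
                    )
                open_holes.discard(int(row.arg))


def read_session_log(path) -> SessionLog:
    """Parse a ``time_s, event, arg`` CSV into a validated :class:`SessionLog`."""
    path = Path(path)
    try:
        ev = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse session log {path}: {exc}")
    missing = [c for c in ("time_s", "event", "arg") if c not in ev.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    unknown = ~ev["event"].isin(EVENT_KINDS)
    if unknown.any():
        line = int(ev.index[unknown][0]) + 2  # header is line 1
        raise FormatError(
            f"{path}, line {line}: unknown event kind {ev['event'][unknown].iloc[0]!r}"
        )
    ev["time_s"] = pd.to_numeric(ev["time_s"], errors="raise").astype(float)
    ev["arg"] = pd.to_numeric(ev["arg"], errors="coerce").astype("Int64")
    t = ev["time_s"].to_numpy()
    if len(t) and not (np.diff(t) >= 0).all():
        if np.diff(t).min() < -TIME_TOLERANCE_S:
            pass  # SessionLog.validate raises with coordinates
        else:
            ev = ev.sort_values("time_s", kind="stable").reset_index(drop=True)
    return SessionLog(ev)


def write_session_log(log: SessionLog, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_tool_comment(config_hash)}\n")
        out = log.events.copy()
        out["time_s"] = out["time_s"].map(lambda v: f"{v:.4f}")
        out.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Screen reports
# ---------------------------------------------------------------------------

SCREEN_REPORT_COLUMNS = [
    "comparison",
    "gene",
    "ge_T",
    "ge_C",
    "expr_T",
    "expr_C",
    "diff_mean",
    "pct_T",
    "pct_C",
    "beta",
    "p_raw",
    "p_bonf",
    "passes_primary",
    "tenfold_flag",
]


def write_screen_report(records: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """Write per-gene x per-comparison screen statistics as a TSV report.

    Rows are ordered deterministically: by comparison name, then descending
    fold-change, then gene symbol.  Floats are printed with 6 significant
    digits so the report round-trips to the precision it states.
    """
    if len(records.columns) == 0:
        records = pd.DataFrame(columns=SCREEN_REPORT_COLUMNS)
    cols = [c for c in SCREEN_REPORT_COLUMNS if c in records.columns]
    extra = [c for c in records.columns if c not in cols]
    out = records[cols + extra].copy()
    if len(out):
        out = out.sort_values(
            ["comparison", "diff_mean", "gene"],
            ascending=[True, False, True],
            kind="stable",
        )
    with open(path, "w") as fh:
        fh.write(f"# {_tool_comment(config_hash)}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_screen_report(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    for col in ("passes_primary", "tenfold_flag"):
        if col in frame.columns:
            frame[col] = frame[col].astype(bool)
    return frame


def read_file_config_hash(path) -> str | None:
    """Extract the ``config=`` hash from a writer's leading comment, if any."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(("#", "%")) and "config=" in first:
        return first.split("config=", 1)[1].split()[0].strip()
    return None
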