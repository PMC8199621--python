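"""Readers and writers for the formats the pipeline touches.

Count matrices follow the CellRanger triplet convention: a Matrix Market
file plus ``features.tsv(.gz)`` and ``barcodes.tsv(.gz)``.  Matrices are
stored **genes x cells** (CellRanger orientation) throughout the package;
every API that consumes a :class:`CountMatrix` assumes this orientation.

The gene axis of a xenograft experiment is species-tagged: features whose
ids start with a configured prefix (by default ``GRCh38_`` for human and
``GRCm38_`` for mouse) are assigned to that genome, and a single designated
feature id (default ``luc+``) marks the luciferase transgene carried only
by the implanted cancer cells.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

SAMPLE_LABELS = ("MsPrim", "MsSec", "MsBlood", "Cult")

#: default feature-id prefix -> species mapping (combined-reference convention)
DEFAULT_SPECIES_PREFIXES: Mapping[str, str] = {"GRCh38_": "human", "GRCm38_": "mouse"}
#: default feature id of the luciferase transgene
DEFAULT_TRANSGENE_ID = "luc+"


class FormatError(ValueError):
    """Raised when an on-disk triplet is internally inconsistent."""


@dataclass
class GeneAxis:
    """Species-tagged gene axis of a combined human/mouse/transgene reference.

    Parameters
    ----------
    gene_id
        Unique feature identifiers (e.g. ``GRCh38_ENSG...`` or ``luc+``).
    gene_symbol
        Display symbols, same length as ``gene_id``.
    species_tag
        One of ``{"human", "mouse", "transgene"}`` per gene.  At most one
        gene may carry the ``transgene`` tag.
    """

    gene_id: np.ndarray
    gene_symbol: np.ndarray
    species_tag: np.ndarray

    def __post_init__(self) -> None:
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.gene_symbol = np.asarray(self.gene_symbol, dtype=object)
        self.species_tag = np.asarray(self.species_tag, dtype=object)
        if not (len(self.gene_id) == len(self.gene_symbol) == len(self.species_tag)):
            raise ValueError("gene axis fields must have equal length")
        if len(set(self.gene_id)) != len(self.gene_id):
            raise ValueError("gene ids must be unique")
        bad = set(self.species_tag) - {"human", "mouse", "transgene"}
        if bad:
            raise ValueError(f"unknown species tags: {sorted(bad)}")
        if int(np.sum(self.species_tag == "transgene")) > 1:
            raise ValueError("at most one gene may be tagged as the transgene")

    def __len__(self) -> int:
        return len(self.gene_id)

    def mask(self, tag: str) -> np.ndarray:
        return self.species_tag == tag

    @property
    def transgene_index(self) -> int | None:
        idx = np.flatnonzero(self.species_tag == "transgene")
        return int(idx[0]) if idx.size else None

    @classmethod
    def from_ids(
        cls,
        gene_ids: Sequence[str],
        gene_symbols: Sequence[str] | None = None,
        prefixes: Mapping[str, str] = DEFAULT_SPECIES_PREFIXES,
        transgene_id: str = DEFAULT_TRANSGENE_ID,
    ) -> "GeneAxis":
        """Infer species tags from feature-id prefixes."""
        tags = []
        for gid in gene_ids:
            if gid == transgene_id:
                tags.append("transgene")
                continue
            for prefix, species in prefixes.items():
                if gid.startswith(prefix):
                    tags.append(species)
                    break
            else:
                raise ValueError(
                    f"feature id {gid!r} matches no species prefix and is not "
                    f"the transgene id {transgene_id!r}"
                )
        if gene_symbols is None:
            gene_symbols = list(gene_ids)
        return cls(np.array(gene_ids, dtype=object),
                   np.array(gene_symbols, dtype=object),
                   np.array(tags, dtype=object))


@dataclass
class CountMatrix:
    """Sparse UMI count matrix (genes x cells) with a species-tagged gene axis."""

    genes: GeneAxis
    barcodes: list[str]
    sample_label: str
    counts: sp.csr_matrix
    gzip_output: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.sample_label not in SAMPLE_LABELS:
            raise ValueError(
                f"sample_label must be one of {SAMPLE_LABELS}, got {self.sample_label!r}"
            )
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} cells"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        if self.counts.nnz and (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def total_umi(self) -> int:
        return int(self.counts.sum())

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the cells in ``index`` (bool or int)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            genes=self.genes,
            barcodes=[self.barcodes[i] for i in index],
            sample_label=self.sample_label,
            counts=self.counts[:, index],
            gzip_output=self.gzip_output,
        )

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            genes=GeneAxis(
                self.genes.gene_id[index],
                self.genes.gene_symbol[index],
                self.genes.species_tag[index],
            ),
            barcodes=list(self.barcodes),
            sample_label=self.sample_label,
            counts=self.counts[index, :],
            gzip_output=self.gzip_output,
        )


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find_triplet_file(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")


def read_mtx_triplet(
    directory: str | Path,
    sample_label: str = "Cult",
    prefixes: Mapping[str, str] = DEFAULT_SPECIES_PREFIXES,
    transgene_id: str = DEFAULT_TRANSGENE_ID,
) -> CountMatrix:
    """Read a CellRanger-style MTX triplet from ``directory``.

    Expects ``matrix.mtx``, ``features.tsv`` and ``barcodes.tsv`` (each
    optionally gzipped).  Species tags are inferred from feature-id prefixes.

    Raises
    ------
    FileNotFoundError
        If any of the three files is absent.
    FormatError
        If the MTX header dimensions disagree with the TSV line counts.
    """
    directory = Path(directory)
    mtx_path = _find_triplet_file(directory, "matrix.mtx")
    feat_path = _find_triplet_file(directory, "features.tsv")
    bc_path = _find_triplet_file(directory, "barcodes.tsv")

    with _open_maybe_gz(mtx_path, "rb") as fh:
        counts = sp.csr_matrix(scipy.io.mmread(fh))
    try:
        features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        features = pd.DataFrame({0: pd.Series(dtype=str)})
    try:
        barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].tolist()
    except pd.errors.EmptyDataError:
        barcodes = []

    if counts.shape[0] != len(features):
        raise FormatError(
            f"matrix has {counts.shape[0]} rows but features.tsv lists "
            f"{len(features)} features"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix has {counts.shape[1]} columns but barcodes.tsv lists "
            f"{len(barcodes)} barcodes"
        )

    symbols = features[1] if features.shape[1] > 1 else features[0]
    genes = GeneAxis.from_ids(
        features[0].tolist(), symbols.tolist(), prefixes=prefixes, transgene_id=transgene_id
    )
    return CountMatrix(genes=genes, barcodes=barcodes,
                       sample_label=sample_label, counts=counts,
                       gzip_output=mtx_path.suffix == ".gz")


def write_mtx_triplet(matrix: CountMatrix, directory: str | Path) -> None:
    """Write ``matrix`` as an MTX triplet readable by :func:`read_mtx_triplet`.

    Honours ``matrix.gzip_output``: when set, ``.gz`` files are emitted.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if matrix.gzip_output else ""

    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(matrix.counts), field="integer")
    opener = gzip.open if matrix.gzip_output else open
    with opener(directory / f"matrix.mtx{suffix}", "wb") as fh:
        fh.write(buf.getvalue())
    feats = pd.DataFrame({
        0: matrix.genes.gene_id,
        1: matrix.genes.gene_symbol,
        2: ["Gene Expression"] * matrix.n_genes,
    })
    feats.to_csv(directory / f"features.tsv{suffix}", sep="\t", header=False, index=False)
    pd.Series(matrix.barcodes).to_csv(
        directory / f"barcodes.tsv{suffix}", sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Cohort tables

COHORT_COLUMNS = [
    "animal_id", "set_id", "G", "HiCi", "blood_volume_ul", "n_lpf",
    "raw_ctc", "raw_cpsc", "last_log10_flux", "recurrence", "progressive",
]


@dataclass
class AnimalRecord:
    """One animal of the preclinical cohort (2x2 factorial design).

    ``G`` and ``HiCi`` are binary treatment flags (gemcitabine and HGF/c-Met
    inhibition); raw rare-cell counts are unadjusted microscope counts which
    :func:`xenopsc.cohort.adjust_rare_cell_count` converts to counts per
    low-powered field per 200 uL of blood.
    """

    animal_id: str
    set_id: str
    G: int
    HiCi: int
    blood_volume_ul: float
    n_lpf: float
    raw_ctc: int
    raw_cpsc: int
    last_log10_flux: float
    recurrence: int
    progressive: int
    tumour_dims_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for flag_name in ("G", "HiCi", "recurrence", "progressive"):
            v = getattr(self, flag_name)
            if v not in (0, 1):
                raise ValueError(f"{flag_name} must be 0 or 1, got {v!r}")
        if self.blood_volume_ul <= 0:
            raise ValueError("blood volume must be positive")
        if self.n_lpf < 1:
            raise ValueError("n_lpf must be >= 1")
        if self.raw_ctc < 0 or self.raw_cpsc < 0:
            raise ValueError("raw counts must be non-negative")


@dataclass
class FluxSeries:
    """Longitudinal log10 ventral radiant flux (p/s) for one animal."""

    animal_id: str
    weeks: np.ndarray
    log10_flux: np.ndarray
    baseline_log10_flux: float

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks)
        self.log10_flux = np.asarray(self.log10_flux, dtype=float)
        if len(self.weeks) != len(self.log10_flux):
            raise ValueError("weeks and flux must have equal length")
        if (self.weeks < 0).any() or not np.array_equal(self.weeks, self.weeks.astype(int)):
            raise ValueError("weeks must be non-negative integers")
        self.weeks = self.weeks.astype(int)


def read_cohort_csv(path: str | Path) -> list[AnimalRecord]:
    """Read a per-animal cohort table (see :data:`COHORT_COLUMNS` for header)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort CSV missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        dims = None
        if {"tumour_l_mm", "tumour_w_mm", "tumour_h_mm"} <= set(df.columns) and not (
            pd.isna(row.get("tumour_l_mm"))
        ):
            dims = (row["tumour_l_mm"], row["tumour_w_mm"], row["tumour_h_mm"])
        records.append(AnimalRecord(
            animal_id=str(row["animal_id"]), set_id=str(row["set_id"]),
            G=int(row["G"]), HiCi=int(row["HiCi"]),
            blood_volume_ul=float(row["blood_volume_ul"]), n_lpf=float(row["n_lpf"]),
            raw_ctc=int(row["raw_ctc"]), raw_cpsc=int(row["raw_cpsc"]),
            last_log10_flux=float(row["last_log10_flux"]),
            recurrence=int(row["recurrence"]), progressive=int(row["progressive"]),
            tumour_dims_mm=dims,
        ))
    return records


def read_flux_csv(path: str | Path) -> list[FluxSeries]:
    """Read long-format flux series: columns animal_id, week, log10_flux."""
    df = pd.read_csv(path)
    need = {"animal_id", "week", "log10_flux"}
    if not need <= set(df.columns):
        raise FormatError(f"flux CSV must have columns {sorted(need)}")
    out = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("week")
        out.append(FluxSeries(
            animal_id=str(animal_id),
            weeks=grp["week"].to_numpy(),
            log10_flux=grp["log10_flux"].to_numpy(),
            baseline_log10_flux=float(grp["log10_flux"].iloc[0]),
        ))
    return out


def cohort_to_frame(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Tabular view of a cohort, one row per animal."""
    return pd.DataFrame([{
        "animal_id": r.animal_id, "set_id": r.set_id, "G": r.G, "HiCi": r.HiCi,
        "blood_volume_ul": r.blood_volume_ul, "n_lpf": r.n_lpf,
        "raw_ctc": r.raw_ctc, "raw_cpsc": r.raw_cpsc,
        "last_log10_flux": r.last_log10_flux,
        "recurrence": r.recurrence, "progressive": r.progressive,
    } for r in records])


def flux_to_frame(series: Sequence[FluxSeries]) -> pd.DataFrame:
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "animal_id": s.animal_id, "week": s.weeks, "log10_flux": s.log10_flux,
            "baseline_log10_flux": s.baseline_log10_flux,
        }))
    return pd.concat(frames, ignore_index=True)
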