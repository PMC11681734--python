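"""Typed readers and writers for the pipeline's tabular formats.

Every table the pipeline touches is plain TSV (tab-separated, UTF-8, ``NA``
as the missing-value token), the dialect of typical omics supplementary
tables.  Readers validate aggressively and hand every downstream module a
typed object whose invariants have already been checked.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_DOSES = (0.0, 10.0, 100.0, 1000.0)
VALID_TIMES = (2.0, 6.0, 24.0)
GROUPS = ("sensitive", "resilient")

RESILIENT_SPECIES = ("mouse", "rat", "rhesus", "baboon")
SENSITIVE_SPECIES = ("rabbit", "pig", "cow", "sheep", "chimpanzee", "human")


class FormatError(ValueError):
    """A file does not parse as the expected TSV layout."""


class ConsistencyError(ValueError):
    """Parsed values violate a cross-record invariant (e.g. species in two groups)."""


class PairingError(ValueError):
    """A stimulated sample lacks its dose-0 control at the same time point."""


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata defining the paired, blocked study design.

    One row per blood sample: which species and individual it came from,
    the species' LPS-lethality group, the ex vivo LPS dose (ng/mL) and the
    incubation time (h).  Dose 0 at a given time is the paired control for
    every stimulated sample of the same individual at that time.
    """

    frame: pd.DataFrame  # columns: sample_id, species, group, individual, dose, time

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def group_of(self, species: str) -> str:
        rows = self.frame.loc[self.frame["species"] == species, "group"]
        if rows.empty:
            raise KeyError(f"unknown species {species!r}")
        return str(rows.iloc[0])

    @property
    def species_groups(self) -> dict[str, str]:
        return {s: self.group_of(s) for s in self.species}

    def subset(self, mask: pd.Series) -> "SampleSheet":
        return SampleSheet(self.frame.loc[mask].reset_index(drop=True))

    def baseline(self, time: float = 2.0) -> "SampleSheet":
        """Unstimulated samples at one time point (default the earliest, 2 h)."""
        f = self.frame
        return self.subset((f["dose"] == 0) & (f["time"] == time))

    def validate(self, require_pairing: bool = True) -> list[str]:
        """Check all invariants; raise on violation, return warnings otherwise."""
        f = self.frame
        warnings: list[str] = []
        dup = f["sample_id"][f["sample_id"].duplicated()]
        if not dup.empty:
            raise FormatError(f"duplicate sample_id(s): {sorted(set(dup))}")
        key = f[["species", "individual", "dose", "time"]]
        if key.duplicated().any():
            raise ConsistencyError("duplicate (species, individual, dose, time) combination")
        bad_group = set(f["group"]) - set(GROUPS)
        if bad_group:
            raise FormatError(f"unknown group label(s): {sorted(bad_group)}")
        ngroups = f.groupby("species")["group"].nunique()
        multi = ngroups[ngroups > 1]
        if not multi.empty:
            raise ConsistencyError(f"species mapped to more than one group: {list(multi.index)}")
        if not f["dose"].isin(VALID_DOSES).all():
            raise FormatError(f"dose outside {VALID_DOSES}")
        if not f["time"].isin(VALID_TIMES).all():
            raise FormatError(f"time outside {VALID_TIMES}")
        controls = set(
            map(tuple, f.loc[f["dose"] == 0, ["species", "individual", "time"]].itertuples(index=False))
        )
        stim = f.loc[f["dose"] > 0, ["species", "individual", "time", "sample_id"]]
        for sp, ind, t, sid in stim.itertuples(index=False):
            if (sp, ind, t) not in controls:
                msg = f"stimulated sample {sid!r} has no dose-0 control for ({sp}, {ind}, t={t})"
                if require_pairing:
                    raise PairingError(msg)
                warnings.append(msg)
        return warnings


@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance table with an explicit missing-value mask.

    ``scale`` is ``"tpm"`` (non-negative transcripts per million) or
    ``"log2"`` (log2(TPM + pseudocount)).  ``missing_mask`` is True where a
    gene has no measurement for a sample, e.g. because the sample's species
    has no annotated ortholog of that gene.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # genes x samples, float
    missing_mask: np.ndarray  # genes x samples, bool
    scale: str = "tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample id lists")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape does not match values")
        if self.scale not in ("tpm", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        obs = self.values[~self.missing_mask]
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValueError("non-finite value outside missing_mask")
        if self.scale == "tpm" and obs.size and (obs < 0).any():
            raise ValueError("negative TPM value")

    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        vals = np.where(self.missing_mask, np.nan, self.values)
        with np.errstate(invalid="ignore"):
            logged = np.log2(vals + pseudocount)
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), np.where(self.missing_mask, 0.0, logged),
            self.missing_mask.copy(), scale="log2",
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx],
            self.missing_mask[:, idx], scale=self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        return df.mask(pd.DataFrame(self.missing_mask, index=self.gene_ids, columns=self.sample_ids))


@dataclass
class ProteinTable:
    """Protein-by-species label-free quantification (LFQ) table.

    ``lfq`` holds log2 LFQ intensities; ``detected`` is False where the
    protein was not observed in that species' plasma (blank/NA in the source
    table).  ``groups`` labels each species sensitive or resilient.
    """

    protein_ids: list[str]
    species_ids: list[str]
    lfq: np.ndarray  # proteins x species, log2 LFQ
    detected: np.ndarray  # proteins x species, bool
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lfq = np.asarray(self.lfq, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.lfq.shape != (len(self.protein_ids), len(self.species_ids)):
            raise ValueError("lfq shape does not match protein/species id lists")
        if self.detected.shape != self.lfq.shape:
            raise ValueError("detected shape does not match lfq")
        if not np.all(np.isfinite(self.lfq[self.detected])):
            raise ValueError("non-finite LFQ among detected cells")
        for sp, g in self.groups.items():
            if g not in GROUPS:
                raise ConsistencyError(f"species {sp!r} has unknown group {g!r}")

    def group_columns(self, group: str) -> list[int]:
        return [j for j, sp in enumerate(self.species_ids) if self.groups.get(sp) == group]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, comment="#", na_filter=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough
        raise FormatError(str(exc)) from exc


def read_sample_sheet(path: str | Path, require_pairing: bool = True) -> SampleSheet:
    """Read and validate a sample sheet TSV.

    Columns: sample_id, species, group, individual, dose, time.  With
    ``require_pairing=False`` missing dose-0 controls only warn, for partial
    designs.
    """
    df = _read_tsv(path)
    required = ["sample_id", "species", "group", "individual", "dose", "time"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing column(s): {missing}")
    try:
        df = df.assign(dose=df["dose"].astype(float), time=df["time"].astype(float))
    except ValueError as exc:
        raise FormatError(f"non-numeric dose/time: {exc}") from exc
    sheet = SampleSheet(df[required].reset_index(drop=True))
    sheet.validate(require_pairing=require_pairing)
    return sheet


def read_expression_matrix(path: str | Path, sheet: SampleSheet | None = None,
                           scale: str = "tpm") -> ExpressionMatrix:
    """Read a gene x sample abundance TSV (first column gene IDs, ``NA`` = missing).

    If ``sheet`` is given, columns must all be samples of the sheet and are
    reordered to the sheet's sample order (restricted to columns present).
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError("expression matrix needs a gene-ID column and at least one sample")
    gene_col = df.columns[0]
    genes = list(df[gene_col])
    if len(set(genes)) != len(genes):
        raise FormatError("duplicate gene IDs")
    sample_cols = list(df.columns[1:])
    if sheet is not None:
        unknown = [c for c in sample_cols if c not in set(sheet.sample_ids)]
        if unknown:
            raise ConsistencyError(f"expression column(s) not in sample sheet: {unknown}")
        sample_cols = [s for s in sheet.sample_ids if s in set(sample_cols)]
    raw = df[sample_cols].to_numpy()
    mask = (raw == "NA") | (raw == "")
    vals = np.zeros(raw.shape, dtype=float)
    try:
        vals[~mask] = raw[~mask].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance value: {exc}") from exc
    return ExpressionMatrix(genes, sample_cols, vals, mask, scale=scale)


def read_protein_table(path: str | Path, groups: Mapping[str, str] | None = None,
                       log2_input: bool = True) -> ProteinTable:
    """Read a protein x species LFQ TSV; blank/NA cells mean 'not detected'.

    ``log2_input=False`` log2-transforms linear intensities at load.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError("protein table needs a protein-ID column and at least one species")
    proteins = list(df[df.columns[0]])
    species = list(df.columns[1:])
    raw = df[species].to_numpy()
    detected = (raw != "NA") & (raw != "")
    lfq = np.zeros(raw.shape, dtype=float)
    try:
        lfq[detected] = raw[detected].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric LFQ value: {exc}") from exc
    if not log2_input:
        if (lfq[detected] <= 0).any():
            raise FormatError("non-positive linear intensity cannot be log2-transformed")
        lfq[detected] = np.log2(lfq[detected])
    return ProteinTable(proteins, species, lfq, detected, groups=dict(groups or {}))


def _format_cell(x: object) -> str:
    if isinstance(x, (bool, np.bool_)):
        return "TRUE" if x else "FALSE"
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return "NA"
        if x == int(x) and abs(x) < 1e15:
            return str(int(x))
        return format(float(x), ".13g")
    if x is None:
        return "NA"
    return str(x)


def write_results_table(results: pd.DataFrame | Iterable, path: str | Path,
                        metadata: Mapping[str, object] | None = None) -> None:
    """Write a results table as TSV with a ``#``-prefixed provenance header.

    Accepts a DataFrame or an iterable of dataclass records.  Floats are
    rendered with 13 significant digits so a write/read round trip reproduces
    values to at least 12; integral floats render without an exponent or
    decimal point.
    """
    if not isinstance(results, pd.DataFrame):
        rows = list(results)
        if rows and dataclasses.is_dataclass(rows[0]):
            results = pd.DataFrame([dataclasses.asdict(r) for r in rows])
        else:
            results = pd.DataFrame(rows)
    from xlps import __version__

    meta = {"pipeline": f"xlps v{__version__}", **(metadata or {})}
    buf = io.StringIO()
    buf.write("# " + "; ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
    buf.write("\t".join(map(str, results.columns)) + "\n")
    for row in results.itertuples(index=False):
        buf.write("\t".join(_format_cell(x) for x in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
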