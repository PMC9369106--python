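"""Count-matrix container and I/O for nCounter-style panel data.

The central in-memory object is :class:`CountMatrix`: a probes x samples
matrix of non-negative counts, where every probe carries one of the four
nCounter probe classes (Endogenous, Housekeeping, Negative, Positive).
Raw counts are integers; normalized matrices may hold fractional values.

Supported on-disk formats:

* RCC — the per-sample instrument file (``<Header>`` / ``<Sample_Attributes>``
  / ``<Lane_Attributes>`` / ``<Code_Summary>`` sections). Read and, for raw
  integer counts only, written.
* a simple CSV dialect: columns ``probe_name, probe_class, <sample>, ...``.
* a two-column label CSV (``sample_id, entity``).
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, OrbitdxError

PROBE_CLASSES = ("Endogenous", "Housekeeping", "Negative", "Positive")

#: canonical write order for probe classes (controls last)
_CLASS_ORDER = {"Endogenous": 0, "Housekeeping": 1, "Negative": 2, "Positive": 3}


@dataclass(frozen=True)
class ProbeDef:
    """A single probe: gene symbol plus nCounter probe class."""

    name: str
    probe_class: str

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(
                f"unknown probe_class {self.probe_class!r} for probe {self.name!r}; "
                f"expected one of {PROBE_CLASSES}"
            )


def fold_code_class(code_class: str) -> str:
    """Map an RCC CodeClass token onto the four canonical probe classes.

    Instrument files use dialect variants such as ``Endogenous1s`` or
    ``Positive1``; these fold onto the canonical class by prefix.
    """
    for canonical in PROBE_CLASSES:
        if code_class.startswith(canonical):
            return canonical
    raise FormatError(f"unrecognised CodeClass {code_class!r}")


@dataclass
class CountMatrix:
    """Probes x samples count matrix with probe-class metadata.

    Parameters
    ----------
    probes
        Ordered probe definitions (names must be unique).
    samples
        Ordered sample identifiers.
    values
        ``(len(probes), len(samples))`` array of non-negative counts.
    """

    probes: list[ProbeDef]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.probes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probes)} probes x {len(self.samples)} samples"
            )
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate probe names: {dup}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative counts are not allowed")

    # -- basic accessors -------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def probe_names(self) -> list[str]:
        return [p.name for p in self.probes]

    @property
    def probe_classes(self) -> np.ndarray:
        return np.array([p.probe_class for p in self.probes])

    def class_index(self, probe_class: str) -> np.ndarray:
        """Row indices of probes of the given class."""
        return np.flatnonzero(self.probe_classes == probe_class)

    def class_values(self, probe_class: str) -> np.ndarray:
        """Sub-matrix of counts for one probe class."""
        return self.values[self.class_index(probe_class)]

    def copy(self) -> "CountMatrix":
        return CountMatrix(list(self.probes), list(self.samples), self.values.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        pos = {s: j for j, s in enumerate(self.samples)}
        cols = [pos[s] for s in sample_ids]
        return CountMatrix(list(self.probes), list(sample_ids), self.values[:, cols])

    def row(self, name: str) -> np.ndarray:
        """Counts of one probe across samples."""
        try:
            i = self.probe_names.index(name)
        except ValueError:
            raise KeyError(f"probe {name!r} not in matrix") from None
        return self.values[i]

    def sample_profile(self, sample: str) -> dict[str, float]:
        """Gene -> count mapping for one sample (Endogenous + Housekeeping)."""
        j = self.samples.index(sample)
        keep = np.isin(self.probe_classes, ("Endogenous", "Housekeeping"))
        return {p.name: self.values[i, j] for i, p in enumerate(self.probes) if keep[i]}

    def to_frame(self) -> pd.DataFrame:
        """DataFrame with probe_name / probe_class columns followed by samples."""
        df = pd.DataFrame(self.values, columns=self.samples)
        df.insert(0, "probe_class", self.probe_classes)
        df.insert(0, "probe_name", self.probe_names)
        return df


def canonical_order(matrix: CountMatrix) -> CountMatrix:
    """Return a copy in canonical probe order.

    Endogenous probes alphabetical by symbol first, then Housekeeping,
    Negative, Positive (each alphabetical) — keeps written files diff-stable.
    """
    order = sorted(
        range(matrix.n_probes),
        key=lambda i: (_CLASS_ORDER[matrix.probes[i].probe_class], matrix.probes[i].name),
    )
    return CountMatrix(
        [matrix.probes[i] for i in order], list(matrix.samples), matrix.values[order]
    )


# ---------------------------------------------------------------------------
# RCC
# ---------------------------------------------------------------------------

def read_rcc(path: str | os.PathLike) -> CountMatrix:
    """Parse a single-sample RCC file into a 1-column :class:`CountMatrix`.

    The sample id is taken from the ``Sample_Attributes`` ``ID`` field,
    falling back to the ``Lane_Attributes`` ``ID`` and finally the filename.
    """
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("</"):
                current = None
            elif line.startswith("<"):
                current = line.strip("<>").strip()
                sections[current] = []
            elif current is not None:
                sections[current].append(line)

    if "Code_Summary" not in sections:
        raise FormatError(f"{path}: RCC file has no Code_Summary section")

    sample_id = None
    for sec in ("Sample_Attributes", "Lane_Attributes"):
        for row in sections.get(sec, []):
            fields = row.split(",")
            if fields and fields[0] == "ID" and len(fields) > 1 and fields[1]:
                sample_id = fields[1]
                break
        if sample_id:
            break
    if not sample_id:
        sample_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]

    probes: list[ProbeDef] = []
    counts: list[float] = []
    for lineno, row in enumerate(sections["Code_Summary"], start=1):
        fields = row.split(",")
        if fields[0] == "CodeClass":  # header row
            continue
        if len(fields) < 4:
            raise FormatError(f"{path}: Code_Summary row {lineno} has <4 fields: {row!r}")
        code_class, name, _accession, count_str = fields[0], fields[1], fields[2], fields[3]
        try:
            count = int(count_str)
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric count {count_str!r} at Code_Summary row {lineno}"
            ) from None
        if count < 0:
            raise FormatError(f"{path}: negative count at Code_Summary row {lineno}")
        probes.append(ProbeDef(name, fold_code_class(code_class)))
        counts.append(count)

    return CountMatrix(probes, [sample_id], np.array(counts, dtype=float)[:, None])


def write_rcc(matrix: CountMatrix, path: str | os.PathLike, sample: str | None = None) -> None:
    """Write one sample of a raw (integer) CountMatrix as an RCC file.

    RCC semantically holds raw instrument counts; fractional (normalized)
    values are rejected — write those through the CSV dialect instead.
    """
    if sample is None:
        if matrix.n_samples != 1:
            raise ValueError("matrix has several samples; pass sample=...")
        sample = matrix.samples[0]
    j = matrix.samples.index(sample)
    col = matrix.values[:, j]
    if not np.allclose(col, np.round(col)):
        raise OrbitdxError("RCC holds raw integer counts; write normalized data as CSV")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("<Header>\nFileVersion,1.7\nSoftwareVersion,orbitdx\n</Header>\n\n")
        fh.write(f"<Sample_Attributes>\nID,{sample}\nOwner,\nComments,\n</Sample_Attributes>\n\n")
        fh.write("<Lane_Attributes>\nID,1\nFovCount,555\nFovCounted,555\n</Lane_Attributes>\n\n")
        fh.write("<Code_Summary>\nCodeClass,Name,Accession,Count\n")
        for probe, count in zip(matrix.probes, col):
            fh.write(f"{probe.probe_class},{probe.name},NA,{int(round(count))}\n")
        fh.write("</Code_Summary>\n")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_counts_csv(path: str | os.PathLike | io.TextIOBase) -> CountMatrix:
    """Read the documented CSV dialect (probe_name, probe_class, samples...)."""
    df = pd.read_csv(path, dtype={"probe_name": str, "probe_class": str})
    if list(df.columns[:2]) != ["probe_name", "probe_class"]:
        raise FormatError("counts CSV must start with probe_name, probe_class columns")
    dup = df["probe_name"][df["probe_name"].duplicated()].tolist()
    if dup:
        raise FormatError(f"duplicate probe rows: {sorted(set(dup))}")
    bad = sorted(set(df["probe_class"]) - set(PROBE_CLASSES))
    if bad:
        raise FormatError(f"unknown probe_class tokens: {bad}")
    probes = [ProbeDef(n, c) for n, c in zip(df["probe_name"], df["probe_class"])]
    samples = list(df.columns[2:])
    values = df[samples].to_numpy(dtype=float) if samples else np.empty((len(probes), 0))
    return CountMatrix(probes, samples, values)


def write_counts_csv(matrix: CountMatrix, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write a CountMatrix in canonical probe order (controls last)."""
    canonical_order(matrix).to_frame().to_csv(path, index=False)


def read_labels_csv(path: str | os.PathLike | io.TextIOBase) -> pd.Series:
    """Read a two-column label CSV into a sample_id -> entity Series."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["sample_id", "entity"]:
        raise FormatError("label CSV must have columns sample_id, entity")
    return pd.Series(df["entity"].values, index=df["sample_id"].values, name="entity")


def write_labels_csv(labels: Mapping[str, str] | pd.Series, path) -> None:
    ser = pd.Series(labels, name="entity")
    ser.rename_axis("sample_id").reset_index().to_csv(path, index=False)
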