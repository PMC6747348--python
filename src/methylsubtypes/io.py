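"""Tabular I/O for the pipeline.

Two external dialects are supported: a GEO-style series-matrix TSV carrying
beta values plus per-sample characteristics rows, and a 450K-manifest-style
probe annotation CSV (``ID`` / ``UCSC_RefGene_Name`` / ``UCSC_RefGene_Group``
columns, semicolon-delimited multi-gene fields).  Everything else is plain
TSV.  Floats are serialized with ``repr`` so write→read round-trips are
lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ProbeAnnotation",
    "read_series_matrix",
    "write_series_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_gene_sets",
    "write_gene_sets",
    "read_ranked_list",
    "write_ranked_list",
    "write_ifs_table",
    "write_confusion",
]

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"
_CHARACTERISTICS = "!Sample_characteristics_ch1"


@dataclass
class BetaMatrix:
    """Samples × probes matrix of methylation beta values with subtype labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_probes)
        Beta values, each in [0, 1].
    sample_ids, probe_ids : sequences of unique strings.
    labels : per-sample subtype name.
    synthetic : optional per-sample flag marking oversampled (non-original)
        samples; defaults to all-False.
    """

    values: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]
    labels: np.ndarray
    synthetic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples × probes array")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.probe_ids) != m:
            raise ValueError(f"{len(self.probe_ids)} probe ids for {m} columns")
        if len(self.labels) != n:
            raise ValueError("labels must have one entry per sample")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(set(self.probe_ids)) != m:
            raise ValueError("probe ids must be unique")
        if any(lab is None or str(lab) == "" for lab in self.labels):
            raise ValueError("missing subtype labels are not supported")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("beta values must be finite (missing values unsupported)")
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")
        if self.synthetic is None:
            self.synthetic = np.zeros(n, dtype=bool)
        else:
            self.synthetic = np.asarray(self.synthetic, dtype=bool)
            if len(self.synthetic) != n:
                raise ValueError("synthetic flags must have one entry per sample")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted({str(l) for l in self.labels})

    def class_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[str(lab)] = out.get(str(lab), 0) + 1
        return dict(sorted(out.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.probe_ids)

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        """Restrict to the given probes, preserving the requested order."""
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in idx]
        if missing:
            raise KeyError(f"unknown probes: {missing[:5]}")
        cols = [idx[p] for p in probe_ids]
        return BetaMatrix(
            self.values[:, cols],
            self.sample_ids,
            list(probe_ids),
            self.labels.copy(),
            self.synthetic.copy(),
        )

    def subset_samples(self, indices) -> "BetaMatrix":
        indices = np.asarray(indices)
        return BetaMatrix(
            self.values[indices],
            [self.sample_ids[i] for i in indices],
            self.probe_ids,
            self.labels[indices],
            self.synthetic[indices],
        )

    def exclude_class(self, label: str) -> "BetaMatrix":
        if label not in self.classes:
            raise KeyError(f"no such class: {label!r}")
        keep = np.flatnonzero(self.labels != label)
        return self.subset_samples(keep)


@dataclass
class ProbeAnnotation:
    """Probe → (gene symbols, region tags) mapping.

    The two lists are parallel: gene ``genes[probe][i]`` is annotated with
    region ``regions[probe][i]``, mirroring the 450K manifest where both
    columns are semicolon-delimited in lock-step.
    """

    genes: dict[str, list[str]] = field(default_factory=dict)
    regions: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, gs in self.genes.items():
            rs = self.regions.get(probe, [])
            if len(gs) != len(rs):
                raise ValueError(f"gene/region lists differ in length for {probe}")
            if any(not g for g in gs):
                raise ValueError(f"empty gene symbol for probe {probe}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.genes)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.genes.values():
            out.update(gs)
        return out


# ----------------------------------------------------------------------
# series-matrix dialect


def _quote(s: str) -> str:
    return f'"{s}"'


def _unquote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        return s[1:-1]
    return s


def write_series_matrix(matrix: BetaMatrix, path) -> None:
    """Write a BetaMatrix in GEO series-matrix layout.

    Subtype labels travel in a ``!Sample_characteristics_ch1`` row as
    ``subtype: <name>``; the oversampling flag in a second characteristics
    row as ``origin: original|synthetic``.
    """
    if len(set(matrix.probe_ids)) != matrix.n_probes:
        raise ValueError("duplicate probe ids")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("!Series_title\t" + _quote("methylation beta values") + "\n")
        fh.write(
            "!Sample_title\t" + "\t".join(_quote(s) for s in matrix.sample_ids) + "\n"
        )
        fh.write(
            _CHARACTERISTICS
            + "\t"
            + "\t".join(_quote(f"subtype: {l}") for l in matrix.labels)
            + "\n"
        )
        fh.write(
            _CHARACTERISTICS
            + "\t"
            + "\t".join(
                _quote(f"origin: {'synthetic' if f else 'original'}")
                for f in matrix.synthetic
            )
            + "\n"
        )
        fh.write(_TABLE_BEGIN + "\n")
        fh.write(
            "\t".join([_quote("ID_REF")] + [_quote(s) for s in matrix.sample_ids])
            + "\n"
        )
        for j, probe in enumerate(matrix.probe_ids):
            row = "\t".join(repr(float(v)) for v in matrix.values[:, j])
            fh.write(_quote(probe) + "\t" + row + "\n")
        fh.write(_TABLE_END + "\n")


def read_series_matrix(path, label_row_key: str = "subtype") -> BetaMatrix:
    """Parse a series-matrix TSV into a samples × probes BetaMatrix.

    ``label_row_key`` names the characteristics key (``key: value``) holding
    the subtype labels; its absence is an error.
    """
    path = Path(path)
    char_rows: list[list[str]] = []
    sample_ids: list[str] | None = None
    probe_ids: list[str] = []
    data_rows: list[np.ndarray] = []
    in_table = False
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(_TABLE_BEGIN):
                in_table = True
                continue
            if line.startswith(_TABLE_END):
                in_table = False
                continue
            fields = line.split("\t")
            if not in_table:
                if fields[0] == _CHARACTERISTICS:
                    char_rows.append([_unquote(f) for f in fields[1:]])
                continue
            if sample_ids is None:
                sample_ids = [_unquote(f) for f in fields[1:]]
                continue
            probe = _unquote(fields[0])
            vals = np.empty(len(fields) - 1)
            for i, cell in enumerate(fields[1:]):
                try:
                    vals[i] = float(cell)
                except ValueError:
                    sid = sample_ids[i] if i < len(sample_ids) else f"column {i}"
                    raise ValueError(
                        f"non-numeric beta value {cell!r} at probe {probe}, "
                        f"sample {sid}"
                    ) from None
            probe_ids.append(probe)
            data_rows.append(vals)
    if sample_ids is None:
        raise ValueError(f"no data table found in {path}")

    def _char_values(key: str) -> list[str] | None:
        prefix = key + ":"
        for row in char_rows:
            if row and all(f.startswith(prefix) for f in row if f):
                return [f[len(prefix) :].strip() for f in row]
        return None

    labels = _char_values(label_row_key)
    if labels is None:
        raise ValueError(
            f"no characteristics row with key {label_row_key!r} found in {path}"
        )
    origin = _char_values("origin")
    synthetic = None
    if origin is not None:
        synthetic = np.array([o == "synthetic" for o in origin])
    values = np.vstack(data_rows).T if data_rows else np.empty((len(sample_ids), 0))
    return BetaMatrix(values, sample_ids, probe_ids, np.array(labels, dtype=object), synthetic)


# ----------------------------------------------------------------------
# probe annotation (450K manifest dialect)

ANNOTATION_COLUMNS = ("ID", "UCSC_RefGene_Name", "UCSC_RefGene_Group")


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    rows = [
        {
            "ID": probe,
            "UCSC_RefGene_Name": ";".join(annotation.genes[probe]),
            "UCSC_RefGene_Group": ";".join(annotation.regions[probe]),
        }
        for probe in annotation.probe_ids
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, index=False)


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read a GPL13534-style annotation CSV.

    Semicolon-delimited gene and region fields are split into parallel lists;
    an empty gene field yields an unannotated probe (empty lists).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"annotation file missing required column {col!r}")
    genes: dict[str, list[str]] = {}
    regions: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        probe = row["ID"]
        gfield = row["UCSC_RefGene_Name"].strip()
        rfield = row["UCSC_RefGene_Group"].strip()
        genes[probe] = gfield.split(";") if gfield else []
        regions[probe] = rfield.split(";") if rfield else []
    return ProbeAnnotation(genes, regions)


# ----------------------------------------------------------------------
# gene-set catalogues


def write_gene_sets(catalogue: dict[str, set], path) -> None:
    """Write a term → gene catalogue as two-column TSV (one gene per row)."""
    with Path(path).open("w") as fh:
        fh.write("term_id\tgene\n")
        for term in sorted(catalogue):
            for gene in sorted(catalogue[term]):
                fh.write(f"{term}\t{gene}\n")


def read_gene_sets(path) -> dict[str, set]:
    """Read a catalogue from two-column TSV or GMT (extension .gmt)."""
    path = Path(path)
    catalogue: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        with path.open() as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                catalogue[parts[0]] = set(g for g in parts[2:] if g)
        return catalogue
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "term_id" not in df.columns or "gene" not in df.columns:
        raise ValueError("gene-set TSV must have 'term_id' and 'gene' columns")
    for term, grp in df.groupby("term_id"):
        catalogue[str(term)] = set(grp["gene"])
    return catalogue


# ----------------------------------------------------------------------
# plain TSV artifacts


def write_ranked_list(path, probe_ids, scores) -> None:
    """Persist an ordered feature list as rank / probe_id / score TSV."""
    with Path(path).open("w") as fh:
        fh.write("rank\tprobe_id\tscore\n")
        for rank, (probe, score) in enumerate(zip(probe_ids, scores), start=1):
            fh.write(f"{rank}\t{probe}\t{repr(float(score))}\n")


def read_ranked_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    for col in ("rank", "probe_id", "score"):
        if col not in df.columns:
            raise ValueError(f"ranked list missing column {col!r}")
    return df


def write_ifs_table(path, evaluations, classes) -> None:
    """Write an incremental-feature-selection sweep as TSV.

    Columns: k, sensitivity_<class>…, specificity_<class>…, accuracy, mcc —
    i.e. 2·C + 3 columns for C classes.
    """
    cols = (
        ["k"]
        + [f"sensitivity_{c}" for c in classes]
        + [f"specificity_{c}" for c in classes]
        + ["accuracy", "mcc"]
    )
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ev in evaluations:
            row = (
                [str(ev.k)]
                + [repr(float(ev.sensitivity[c])) for c in classes]
                + [repr(float(ev.specificity[c])) for c in classes]
                + [repr(float(ev.accuracy)), repr(float(ev.mcc))]
            )
            fh.write("\t".join(row) + "\n")


def write_confusion(path, confusion: pd.DataFrame) -> None:
    """Write a C × C confusion matrix (rows = true class) as TSV."""
    confusion.to_csv(path, sep="\t", index_label="true\\pred")


def read_confusion(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
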