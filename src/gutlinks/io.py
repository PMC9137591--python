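"""Readers, writers and validated containers for count tables, taxonomy,
sample metadata, trees and configuration.

File conventions
----------------
* Count table: TSV, features as rows (amplicon convention), first column the
  feature id, header row the sample ids, cells non-negative integers.
* Taxonomy: TSV with two columns, feature id and a semicolon-separated
  lineage (``Bacteria;Firmicutes;Bacilli;...``). Optional QIIME-style rank
  prefixes (``g__``) are stripped. Lineages shorter than seven ranks are
  padded with ``Unclassified``.
* Metadata: TSV with columns ``sample_id, bird_id, place, bw_group,
  body_weight_g``; ``place`` is one of JC/JM/CC (jejunum chymus, jejunum
  mucosa, caecum chymus) and ``bw_group`` one of LBW/HBW.
* Tree: rooted Newick.

All validation is total: malformed input raises :class:`TableIOError` with
the offending location, never a silent coercion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

PLACES = ("JC", "JM", "CC")
BW_GROUPS = ("LBW", "HBW")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "Unclassified"


class TableIOError(ValueError):
    """Malformed input file; message names the offending location."""


# ---------------------------------------------------------------------------
# CountTable


class CountTable:
    """Feature-by-sample matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        2-D array-like of shape (n_features, n_samples).
    feature_ids, sample_ids
        Unique identifiers for rows and columns.
    """

    def __init__(self, counts, feature_ids, sample_ids):
        counts = np.asarray(counts)
        feature_ids = [str(f) for f in feature_ids]
        sample_ids = [str(s) for s in sample_ids]
        if counts.ndim != 2:
            raise TableIOError("counts must be 2-D")
        if counts.shape != (len(feature_ids), len(sample_ids)):
            raise TableIOError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        if len(set(feature_ids)) != len(feature_ids):
            dup = _first_duplicate(feature_ids)
            raise TableIOError(f"duplicate feature id {dup!r}")
        if len(set(sample_ids)) != len(sample_ids):
            dup = _first_duplicate(sample_ids)
            raise TableIOError(f"duplicate sample id {dup!r}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                i, j = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise TableIOError(
                    f"non-integer count {counts[i, j]} at feature "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise TableIOError(
                f"negative count at feature {feature_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        self.feature_ids = feature_ids
        self.sample_ids = sample_ids

    # -- basic protocol -----------------------------------------------------

    @property
    def shape(self):
        return self.counts.shape

    @property
    def n_features(self):
        return self.counts.shape[0]

    @property
    def n_samples(self):
        return self.counts.shape[1]

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def feature_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(frame.to_numpy(), list(frame.index), list(frame.columns))

    def select_samples(self, sample_ids) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(self.counts[:, idx], self.feature_ids, list(sample_ids))

    def select_features(self, feature_ids) -> "CountTable":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return CountTable(self.counts[idx, :], list(feature_ids), self.sample_ids)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundance as fractions summing to 1."""
        sums = self.sample_sums().astype(float)
        if np.any(sums == 0):
            j = int(np.argmax(sums == 0))
            raise TableIOError(f"sample {self.sample_ids[j]!r} has zero total count")
        return pd.DataFrame(
            self.counts / sums, index=self.feature_ids, columns=self.sample_ids
        )

    def __eq__(self, other):
        return (
            isinstance(other, CountTable)
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self):
        return f"CountTable({self.n_features} features x {self.n_samples} samples)"


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)


def read_count_table(path) -> CountTable:
    """Read a TSV count table (features as rows, first column feature id)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise TableIOError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        feature_ids = []
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise TableIOError(
                    f"{path}:{lineno}: expected {len(cols)} columns, got {len(parts)}"
                )
            feature_ids.append(parts[0])
            row = []
            for sample, cell in zip(sample_ids, parts[1:]):
                try:
                    value = int(cell)
                except ValueError:
                    raise TableIOError(
                        f"{path}:{lineno}: non-integer count {cell!r} for feature "
                        f"{parts[0]!r}, sample {sample!r}"
                    ) from None
                row.append(value)
            rows.append(row)
    counts = np.array(rows, dtype=np.int64).reshape(len(feature_ids), len(sample_ids))
    try:
        return CountTable(counts, feature_ids, sample_ids)
    except TableIOError as exc:
        raise TableIOError(f"{path}: {exc}") from None


def write_count_table(table: CountTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature_id\t" + "\t".join(table.sample_ids) + "\n")
        for fid, row in zip(table.feature_ids, table.counts):
            fh.write(fid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata

METADATA_COLUMNS = ["sample_id", "bird_id", "place", "bw_group", "body_weight_g"]


def validate_metadata(meta: pd.DataFrame, source: str = "metadata") -> pd.DataFrame:
    """Validate a sample metadata frame and return it with typed columns.

    Enforces the closed place/bw_group vocabularies, positive body weights
    and uniqueness of (bird_id, place) and of sample_id.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TableIOError(f"{source}: missing column(s) {', '.join(missing)}")
    meta = meta.loc[:, METADATA_COLUMNS].copy()
    for col in ("sample_id", "bird_id", "place", "bw_group"):
        meta[col] = meta[col].astype(str)
    bad_place = sorted(set(meta["place"]) - set(PLACES))
    if bad_place:
        raise TableIOError(
            f"{source}: unknown place label(s) {bad_place}; expected one of {PLACES}"
        )
    bad_group = sorted(set(meta["bw_group"]) - set(BW_GROUPS))
    if bad_group:
        raise TableIOError(
            f"{source}: unknown bw_group label(s) {bad_group}; "
            f"expected one of {BW_GROUPS}"
        )
    try:
        meta["body_weight_g"] = meta["body_weight_g"].astype(float)
    except ValueError as exc:
        raise TableIOError(f"{source}: non-numeric body_weight_g ({exc})") from None
    if (meta["body_weight_g"] <= 0).any():
        bad = meta.loc[meta["body_weight_g"] <= 0, "sample_id"].iloc[0]
        raise TableIOError(f"{source}: non-positive body_weight_g for sample {bad!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableIOError(f"{source}: duplicate sample_id {dup!r}")
    if meta.duplicated(subset=["bird_id", "place"]).any():
        row = meta[meta.duplicated(subset=["bird_id", "place"])].iloc[0]
        raise TableIOError(
            f"{source}: duplicate (bird_id, place) pair "
            f"({row['bird_id']!r}, {row['place']!r})"
        )
    return meta.reset_index(drop=True)


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta, source=str(path))


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy

_RANK_PREFIXES = tuple(f"{r[0]}__" for r in RANKS) + ("d__",)


def parse_lineage(lineage: str) -> tuple:
    """Parse a semicolon-separated lineage into the 7-rank tuple.

    Rank prefixes (``k__``, ``p__``, ... ``d__``) are stripped; empty or
    missing levels become ``Unclassified``.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    cleaned = []
    for p in parts:
        for pref in _RANK_PREFIXES:
            if p.startswith(pref):
                p = p[len(pref):]
                break
        cleaned.append(p if p else UNCLASSIFIED)
    if len(cleaned) > len(RANKS):
        raise TableIOError(
            f"lineage has {len(cleaned)} levels, more than the {len(RANKS)} ranks: "
            f"{lineage!r}"
        )
    cleaned += [UNCLASSIFIED] * (len(RANKS) - len(cleaned))
    return tuple(cleaned)


def read_taxonomy(path) -> pd.DataFrame:
    """Read a two-column TSV (feature id, lineage) into a rank table.

    Returns a DataFrame indexed by feature id with the seven rank columns.
    """
    path = Path(path)
    records = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TableIOError(f"{path}:{lineno}: expected 'id<TAB>lineage'")
            fid = parts[0]
            if fid == "feature_id":  # optional header
                continue
            if fid in records:
                raise TableIOError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            try:
                records[fid] = parse_lineage(parts[1])
            except TableIOError as exc:
                raise TableIOError(f"{path}:{lineno}: {exc}") from None
    return pd.DataFrame.from_dict(records, orient="index", columns=list(RANKS))


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("feature_id\tlineage\n")
        for fid, row in tax.iterrows():
            fh.write(f"{fid}\t" + ";".join(row.tolist()) + "\n")


def taxonomy_for(tax: pd.DataFrame, feature_ids) -> pd.DataFrame:
    """Taxonomy rows for the given features; unmapped ids are Unclassified."""
    rows = []
    for fid in feature_ids:
        if fid in tax.index:
            rows.append(tax.loc[fid].tolist())
        else:
            rows.append([UNCLASSIFIED] * len(RANKS))
    return pd.DataFrame(rows, index=list(feature_ids), columns=list(RANKS))


# ---------------------------------------------------------------------------
# Tree


def read_tree(path):
    """Read a rooted Newick tree as an skbio TreeNode."""
    from skbio import TreeNode

    path = Path(path)
    text = path.read_text().strip()
    if not text.endswith(";"):
        raise TableIOError(f"{path}: Newick string must end with ';'")
    try:
        tree = TreeNode.read([text])
    except Exception as exc:
        raise TableIOError(f"{path}: could not parse Newick ({exc})") from None
    return tree


def write_tree(newick: str, path) -> None:
    Path(path).write_text(newick.rstrip() + ("\n" if not newick.endswith("\n") else ""))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class Config:
    """Analysis thresholds, with the study's published defaults.

    Attributes
    ----------
    rarefaction_depth : reads per sample after rarefaction.
    min_feature_reads : minimum total reads across all samples to keep a
        feature (the ``>= 10`` retention rule).
    shannon_log_base : base of the Shannon-index logarithm.
    n_permutations : label permutations for PERMANOVA/ANOSIM/CCA.
    cooc_prevalence_min : samples (of the group's 5) in which a genus must be
        non-zero to enter a co-occurrence network.
    cooc_edge_rho_min : |rho| threshold for calling a network edge.
    cooc_mc_reps : Monte Carlo replicates for degree/component significance.
    trait_min_mean_abundance : mean relative-abundance fraction a genus must
        exceed to enter the body-weight correlation screen (0.0001 = 0.01%).
    trait_min_prevalence : samples in which the genus must be non-zero.
    alpha : significance level.
    trend_band : FDR p interval reported as a trend.
    """

    rarefaction_depth: int = 10_000
    min_feature_reads: int = 10
    shannon_log_base: float = 2.0
    n_permutations: int = 999
    cooc_prevalence_min: int = 4
    cooc_edge_rho_min: float = 0.9
    cooc_mc_reps: int = 1000
    trait_min_mean_abundance: float = 0.0001
    trait_min_prevalence: int = 8
    alpha: float = 0.05
    trend_band: tuple = (0.05, 0.10)
    seed: int = 0

    def __post_init__(self):
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if self.min_feature_reads < 0:
            raise ValueError("min_feature_reads must be >= 0")
        if self.shannon_log_base <= 1:
            raise ValueError("shannon_log_base must be > 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 <= self.cooc_edge_rho_min:
            raise ValueError("cooc_edge_rho_min must be >= 0")
        if self.cooc_mc_reps < 100:
            raise ValueError("cooc_mc_reps must be >= 100")
        if not 0 <= self.trait_min_mean_abundance < 1:
            raise ValueError("trait_min_mean_abundance must be a fraction in [0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        self.trend_band = tuple(self.trend_band)
        if not (0 < self.trend_band[0] < self.trend_band[1] <= 1):
            raise ValueError("trend_band must be an ordered interval in (0,1]")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise TableIOError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["trend_band"] = list(self.trend_band)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Misc result IO


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
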