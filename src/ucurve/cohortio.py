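"""Readers/writers, run configuration, seeds, and friendship-network degrees.

Cohort and region tables travel as TSV with a header row; ground truth as a
flat YAML file; atlas labels as a two-column TSV (region_id, region_name).
The directed friendship network is an edge list of (nominator, nominee)
pairs from a capped-nomination survey; per-node outdegree counts
nominations made (sociability), indegree nominations received (popularity),
and reciprocal degree the outward nominations returned by the nominee.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ucurve")


@dataclass
class RunConfig:
    """Validated run settings; every run writes the resolved copy next to
    its outputs."""

    input_path: str = ""
    region_path: str = ""
    atlas_path: str = ""
    output_dir: str = "ucurve_out"
    predictor: str = "count"
    outcomes: tuple = ("outcome",)
    covariates: tuple = ()
    neuro_covariates: tuple = ()       # extra: handedness, motion, manufacturer
    alpha: float = 0.05
    m_bonferroni: int | None = None
    bin_edges: tuple | None = None
    breakpoint: float | None = None
    family_column: str | None = None   # one-child-per-family hook; inert if absent
    nomination_cap: int = 10
    n_boot: int = 10_000
    n_perm: int = 5000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("n_boot and n_perm must be positive")
        if self.nomination_cap < 1:
            raise ValueError("nomination_cap must be positive")
        self.outcomes = tuple(self.outcomes)
        self.covariates = tuple(self.covariates)
        self.neuro_covariates = tuple(self.neuro_covariates)
        if self.bin_edges is not None:
            self.bin_edges = tuple(float(b) for b in self.bin_edges)
            if any(b2 <= b1 for b1, b2 in zip(self.bin_edges, self.bin_edges[1:])):
                raise ValueError("bin_edges must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def write_resolved(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "resolved_config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)
        return path


def read_table(path) -> pd.DataFrame:
    """Delimiter-robust table read (TSV default, CSV fallback)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return df


def read_cohort(path, config: RunConfig) -> pd.DataFrame:
    """Read a cohort table and validate the column-role bindings."""
    df = read_table(path)
    needed = [config.predictor, *config.outcomes, *config.covariates]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"cohort table is missing bound columns: {missing}")
    if "subject_id" in df.columns and df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id values in cohort table")
    if (df[config.predictor] < 0).any():
        raise ValueError("negative friend counts in cohort table")
    if "count_log" not in df.columns:
        df["count_log"] = np.log10(df[config.predictor].astype(float) + 1.0)
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def write_results(out_dir, tables: dict, config: RunConfig | None = None) -> dict:
    """Write a dict of name -> DataFrame as TSVs plus the resolved config."""
    out = Path(out_dir)
    paths = {}
    for name, df in tables.items():
        paths[name] = write_table(df, out / f"{name}.tsv",
                                  index=df.index.name is not None)
    if config is not None:
        paths["config"] = config.write_resolved(out)
    logger.info("wrote %d tables to %s (seed=%s)", len(tables), out,
                getattr(config, "seed", "n/a"))
    return paths


def write_atlas(labels, path) -> Path:
    df = pd.DataFrame({"region_id": range(1, len(labels) + 1),
                       "region_name": labels})
    return write_table(df, path)


def read_atlas(path) -> list[str]:
    return read_table(path)["region_name"].astype(str).tolist()


def select_one_per_family(df: pd.DataFrame, family_column: str | None,
                          seed: int = 0) -> pd.DataFrame:
    """Keep one randomly chosen row per family; inert without the column."""
    if family_column is None or family_column not in df.columns:
        return df
    rng = np.random.default_rng(seed)
    picks = (df.sample(frac=1.0, random_state=rng.integers(2**31))
               .groupby(family_column, sort=False).head(1))
    return picks.sort_index()


def compute_degrees(edges, roster=None, nomination_cap: int | None = 10) -> pd.DataFrame:
    """Per-node outdegree, indegree and reciprocal degree of a directed
    friendship-nomination network.

    ``edges`` is an iterable of (nominator, nominee) pairs or a two-column
    DataFrame.  Duplicate identical edges are deduplicated with a warning;
    self-nominations raise.  Reciprocal degree counts, per node, the
    outgoing edges whose reverse edge exists (once per ordered outgoing
    edge).
    """
    if isinstance(edges, pd.DataFrame):
        pairs = [tuple(r) for r in edges.iloc[:, :2].itertuples(index=False)]
    else:
        pairs = [tuple(e) for e in edges]
    if any(u == v for u, v in pairs):
        raise ValueError("self-nominations are not allowed")
    unique = set(pairs)
    if len(unique) < len(pairs):
        warnings.warn(f"{len(pairs) - len(unique)} duplicate edges removed",
                      stacklevel=2)
    edge_set = unique
    nodes = set(roster) if roster is not None else set()
    if roster is not None:
        known = {(u, v) for u, v in edge_set if u in nodes and v in nodes}
        dropped = len(edge_set) - len(known)
        if dropped:
            logger.info("dropped %d edges to unknown ids", dropped)
        edge_set = known
    else:
        for u, v in edge_set:
            nodes.add(u)
            nodes.add(v)
    out = {n: 0 for n in nodes}
    ind = {n: 0 for n in nodes}
    rec = {n: 0 for n in nodes}
    for u, v in edge_set:
        out[u] += 1
        ind[v] += 1
        if (v, u) in edge_set:
            rec[u] += 1
    if nomination_cap is not None:
        over = [n for n, d in out.items() if d > nomination_cap]
        if over:
            raise ValueError(f"nodes exceed the nomination cap of "
                             f"{nomination_cap}: {sorted(over)[:5]}")
    idx = sorted(nodes)
    return pd.DataFrame({"outdegree": [out[n] for n in idx],
                         "indegree": [ind[n] for n in idx],
                         "reciprocal_degree": [rec[n] for n in idx]},
                        index=pd.Index(idx, name="node"))


def write_json(payload: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return path
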