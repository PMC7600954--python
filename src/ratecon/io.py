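"""Configuration, clade files, and provenance-stamped writers."""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import Alignment, read_alignment  # re-exported
from .errors import InvalidArgumentError
from .mcmc import MCMCConfig, Trace
from .trees import TimeTree, read_tree, write_nexus_trees  # re-exported

__all__ = ["RunConfig", "read_alignment", "read_tree", "read_clades",
           "write_clades", "provenance_header", "write_tsv",
           "write_trace_tsv", "write_tree_log"]


@dataclass
class RunConfig:
    """Settings for the end-to-end pipeline."""

    alignment: str = ""
    alignment_format: str = "fasta"
    frame_offset: int = 0
    constraint_tree: str = ""
    tree_format: str = "newick"
    clade_file: str = ""
    focal_clade: str = ""
    output_dir: str = "ratecon_out"
    seed: int = 0
    # saturation stage
    p_inv_source: str = "empirical"   # 'empirical' or a fixed float as string
    include_threshold: float = 0.01
    run_iss: bool = True
    iss_replicates: int = 100
    iss_sim_replicates: int = 12
    # MCMC stage
    generations: int = 500_000
    sample_every: int = 100
    burnin_fraction: float = 0.10
    hpd_prob: float = 0.95
    ess_threshold: float = 200.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise InvalidArgumentError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(generations=self.generations,
                          sample_every=self.sample_every,
                          burnin_fraction=self.burnin_fraction,
                          seed=self.seed)

    def resolve_p_inv(self, aln: Alignment) -> float:
        if self.p_inv_source == "empirical":
            return aln.proportion_invariant()
        try:
            return float(self.p_inv_source)
        except ValueError as exc:
            raise InvalidArgumentError(
                f"p_inv_source must be 'empirical' or a number, got "
                f"{self.p_inv_source!r}") from exc


def provenance_header(config_hash: str, seed: int) -> list[str]:
    return [f"ratecon {__version__}", f"config {config_hash}", f"seed {seed}"]


def read_clades(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse a clade-definition file: ``Name: taxon1, taxon2, ...`` lines."""
    clades: dict[str, frozenset[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise InvalidArgumentError(
                f"{path}:{ln}: expected 'Name: taxon, taxon, ...'")
        name, rest = line.split(":", 1)
        name = name.strip()
        taxa = frozenset(t.strip() for t in rest.split(",") if t.strip())
        if not name or not taxa:
            raise InvalidArgumentError(f"{path}:{ln}: empty clade definition")
        if name in clades:
            raise InvalidArgumentError(f"{path}:{ln}: duplicate clade {name!r}")
        clades[name] = taxa
    if not clades:
        raise InvalidArgumentError(f"{path}: no clades defined")
    return clades


def write_clades(clades: dict[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(clades):
            fh.write(f"{name}: {', '.join(sorted(clades[name]))}\n")


def write_tsv(df: pd.DataFrame, path: str | Path,
              header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_trace_tsv(trace: Trace, path: str | Path,
                    header_lines: list[str]) -> None:
    write_tsv(trace.scalars, path, header_lines)


def write_tree_log(trace: Trace, path: str | Path,
                   header_lines: list[str], thin: int = 1) -> None:
    """NEXUS tree log with BEAST-style bracketed branch-rate comments."""
    gens = trace.scalars["state"].to_numpy().astype(int)
    trees = [(f"STATE_{gens[i]}", trace.tree_at(i))
             for i in range(0, trace.n_samples, thin)]
    write_nexus_trees(trees, path, include_rates=True,
                      header_lines=header_lines)
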