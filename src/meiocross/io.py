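"""Delimited-text and config plumbing.

Every table written by the pipeline is tab-separated text with a provenance
header of ``# key = value`` lines (stage, seed, parameters) followed by a
normal header row; :func:`read_tsv` round-trips both parts losslessly.
Configs (karyotype, genotypes, stage parameters) are YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .meiosis import GenotypeSpec, Karyotype

__all__ = [
    "write_tsv",
    "read_tsv",
    "load_config",
    "dump_config",
    "karyotype_from_config",
    "genotype_from_config",
    "params_from_config",
    "write_sc_state",
]


def write_tsv(df: pd.DataFrame, path, meta: Mapping[str, Any] | None = None) -> None:
    """Write a table as TSV with ``# key = value`` provenance lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_tsv`; returns (table, meta)."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def dump_config(cfg: Mapping, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def karyotype_from_config(cfg: Mapping) -> Karyotype:
    """Karyotype from a config mapping with a ``karyotype`` section."""
    if "karyotype" not in cfg:
        raise ValueError("config has no 'karyotype' section")
    return Karyotype.from_dict(cfg["karyotype"])


def params_from_config(cfg: Mapping) -> "CoarseningParams":
    """Coarsening parameters from the optional ``coarsening`` config section.

    Keys mirror the :class:`~meiocross.coarsening.CoarseningParams` field
    names; absent keys keep their defaults.
    """
    from .coarsening import CoarseningParams

    section = dict(cfg.get("coarsening", {}))
    valid = {f.name for f in dataclasses.fields(CoarseningParams)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown coarsening parameters: {sorted(unknown)}")
    return CoarseningParams(**section)


def write_sc_state(state, prefix) -> None:
    """Debug snapshot of one SC state as two delimited-text tables.

    ``<prefix>.concentration.tsv`` holds (position_um, concentration) per
    grid node; ``<prefix>.foci.tsv`` holds (position_um, amount) per focus.
    """
    import numpy as np

    prefix = Path(prefix)
    meta = {"sc_length_um": state.sc_length, "time_s": state.time}
    nodes = pd.DataFrame(
        {
            "position_um": np.arange(state.n_grid) * state.dx,
            "concentration": state.concentration,
        }
    )
    write_tsv(nodes, prefix.with_suffix(".concentration.tsv"), meta)
    foci = pd.DataFrame({"position_um": state.positions, "amount": state.amounts})
    write_tsv(foci, prefix.with_suffix(".foci.tsv"), meta)


def genotype_from_config(cfg: Mapping, name: str) -> GenotypeSpec:
    """Genotype ``name`` from the ``genotypes`` section of a config."""
    section = cfg.get("genotypes", {})
    if name not in section:
        raise ValueError(f"genotype {name!r} not present in config")
    g = dict(section[name])
    return GenotypeSpec(
        name=name,
        dosage_factor=g.get("dosage_factor"),
        zyp1=bool(g.get("zyp1", False)),
        sex=g.get("sex", "female"),
        poisson_means=g.get("poisson_means"),
    )
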