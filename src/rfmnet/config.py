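"""Network configuration files and result serialization.

A network config is a YAML (or JSON) document::

    version: 1
    s: 50.0
    chains:
      - rates: [1.0, 1.0, 1.0]     # lambda_0..lambda_n, 1/s
        copies: 100                # identical-chain shorthand, default 1
        pool_function:
          family: linear           # or tanh
          slope: 1.0               # tanh: alpha, beta

Unknown keys are rejected (fail-fast) and validation errors name the
offending chain and field.  Results are written as tidy CSV/TSV with a
``#``-prefixed metadata header (config hash, seed) or as a JSON summary.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import RateProfile
from .pool import ChainGroup, NetworkSpec, NetworkEquilibrium, PoolFunction

__all__ = [
    "read_network_config",
    "write_network_config",
    "read_rate_profile_tsv",
    "spec_hash",
    "write_results",
    "read_table",
]

SCHEMA_VERSION = 1
_POOL_KEYS = {"linear": {"slope"}, "tanh": {"alpha", "beta"}}


class ConfigError(ValueError):
    """A config file violates the schema."""


def _require_keys(mapping: dict, allowed: set, required: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise ConfigError(f"{where}: missing keys {sorted(missing)}")


def _parse_pool_function(node, where: str) -> PoolFunction:
    if not isinstance(node, dict) or "family" not in node:
        raise ConfigError(f"{where}: pool_function must be a mapping with a 'family' key")
    family = node["family"]
    if family not in _POOL_KEYS:
        raise ConfigError(f"{where}: unknown pool_function family {family!r}")
    _require_keys(node, _POOL_KEYS[family] | {"family"}, _POOL_KEYS[family] | {"family"}, where)
    try:
        if family == "linear":
            return PoolFunction.linear(float(node["slope"]))
        return PoolFunction.tanh(float(node["alpha"]), float(node["beta"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def read_network_config(path) -> NetworkSpec:
    """Load and validate a network spec from a YAML/JSON config file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    _require_keys(doc, {"version", "s", "chains"}, {"version", "s", "chains"}, str(path))
    if doc["version"] != SCHEMA_VERSION:
        raise ConfigError(f"{path}: unsupported config version {doc['version']!r}")
    try:
        s = float(doc["s"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: field 's' must be a number") from exc
    chains = doc["chains"]
    if not isinstance(chains, list) or not chains:
        raise ConfigError(f"{path}: 'chains' must be a nonempty list")
    groups = []
    for idx, node in enumerate(chains):
        where = f"{path}: chains[{idx}]"
        if not isinstance(node, dict):
            raise ConfigError(f"{where}: must be a mapping")
        _require_keys(node, {"rates", "copies", "pool_function"}, {"rates", "pool_function"}, where)
        try:
            profile = RateProfile(node["rates"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{where}: invalid rates: {exc}") from exc
        copies = node.get("copies", 1)
        if not isinstance(copies, int) or copies < 1:
            raise ConfigError(f"{where}: copies must be a positive integer, got {copies!r}")
        pool_fn = _parse_pool_function(node["pool_function"], where)
        groups.append(ChainGroup(profile, pool_fn, copies))
    try:
        return NetworkSpec(tuple(groups), s)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _spec_document(spec: NetworkSpec) -> dict:
    return {
        "version": SCHEMA_VERSION,
        "s": spec.s,
        "chains": [
            {
                "rates": list(g.profile.rates),
                "copies": g.copies,
                "pool_function": {"family": g.pool_fn.family, **dict(g.pool_fn.params)},
            }
            for g in spec.groups
        ],
    }


def write_network_config(spec: NetworkSpec, path) -> None:
    """Serialize a spec back to YAML (round-trips through the reader)."""
    for g in spec.groups:
        if g.pool_fn.family == "custom":
            raise ConfigError("custom pool functions cannot be serialized to a config file")
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_document(spec), fh, sort_keys=False)


def read_rate_profile_tsv(path) -> RateProfile:
    """Read a chain's rates from a two-column TSV of (site index, rate)."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None, names=["index", "rate"])
    table = table.sort_values("index")
    expected = list(range(len(table)))
    if list(table["index"]) != expected:
        raise ConfigError(
            f"{path}: rate indices must be 0..n without gaps, got {list(table['index'])}"
        )
    return RateProfile(table["rate"].to_numpy())


def spec_hash(spec: NetworkSpec) -> str:
    """Stable short hash of the network spec, for result provenance."""
    payload = json.dumps(_spec_document(spec), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _metadata_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in metadata.items())


def _equilibrium_frame(result: NetworkEquilibrium) -> pd.DataFrame:
    rows = []
    chain_idx = 0
    for eq, copies in zip(result.group_equilibria, result.copies):
        for _ in range(copies):
            for site, ej in enumerate(eq.e, start=1):
                rows.append(
                    {"chain": chain_idx, "site": site, "density": ej, "R": eq.R}
                )
            chain_idx += 1
    frame = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [{"chain": -1, "site": 0, "density": result.e_z, "R": result.TPR}]
    )
    return pd.concat([frame, summary], ignore_index=True)


def write_results(result, path, fmt: str = "csv", metadata: dict | None = None) -> None:
    """Write an equilibrium or a tidy table to ``path``.

    ``result`` is either a :class:`NetworkEquilibrium` (CSV/TSV: one row per
    (chain, site) plus a summary row with chain = -1 holding ``e_z`` and
    TPR; JSON: a summary object) or a DataFrame (written as-is).  CSV/TSV
    files start with ``#``-prefixed metadata lines (seed, config hash, ...)
    and carry full float precision.
    """
    if fmt not in ("csv", "tsv", "json"):
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    if fmt == "json":
        if isinstance(result, NetworkEquilibrium):
            doc = {
                "e_z": result.e_z,
                "TPR": result.TPR,
                "q": result.q,
                "s": result.s,
                "chains": [
                    {"copies": c, "R": eq.R, "e": list(np.asarray(eq.e))}
                    for eq, c in zip(result.group_equilibria, result.copies)
                ],
            }
        else:
            doc = result.to_dict(orient="records")
        if metadata:
            doc = {"metadata": metadata, "result": doc}
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return
    frame = _equilibrium_frame(result) if isinstance(result, NetworkEquilibrium) else result
    sep = "," if fmt == "csv" else "\t"
    buf = io.StringIO()
    frame.to_csv(buf, sep=sep, index=False, float_format="%.17g")
    path.write_text(_metadata_lines(metadata) + buf.getvalue())


def read_table(path, fmt: str = "csv") -> pd.DataFrame:
    """Read back a table written by :func:`write_results` (skips metadata)."""
    sep = "," if fmt == "csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#")
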