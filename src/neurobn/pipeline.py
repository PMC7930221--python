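"""Study orchestration: per-group, per-subset learning and cross-group comparison.

``run_study`` reproduces the full comparative design from one JSON config:
for every group x variable-subset it estimates bootstrap arc confidences,
builds the blacklist, learns the definitive structure by tabu search, fits
parameters, and exports the CPDAG, precision matrix and partial
correlations; for every subset it then compares the two groups (Hellinger
distances with mean-refitting, common CPDAG arcs, Markov-blanket
agreement).  Subsets flagged ``correlation_network`` additionally export
thresholded marginal-correlation graphs.  A manifest records the config,
every derived seed and a SHA-256 hash of each artifact, so a rerun with the
same seed is verifiably identical.

The master seed fans out to named substreams (group/subset), so adding a
subset never perturbs existing results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._utils import standardize, substream_seed
from .bootstrap import arc_confidence, bootstrap_networks, build_blacklist
from .compare import compare_networks, correlation_network, welch_t_table
from .gbn import fit_parameters, partial_correlations, precision_matrix
from .graphs import dag_to_cpdag
from .learn import SearchConfig, tabu_search
from .synthetic import make_confidence_scenario

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    groups: dict  # name -> {"table": csv path} or {"synthetic": {"n":..,"N":..}}
    subsets: dict[str, list[str]]
    output_dir: str
    bootstrap_replicates: int = 2000
    confidence_threshold: float = 0.7
    tabu_list_size: int = 30
    max_nonimproving: int = 30
    correlation_thresholds: dict[str, float] = field(default_factory=dict)
    correlation_network_subsets: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must be in [0, 1]")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        obj = json.loads(Path(path).read_text())
        return cls(**obj)

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": self.groups,
                "subsets": self.subsets,
                "output_dir": str(self.output_dir),
                "bootstrap_replicates": self.bootstrap_replicates,
                "confidence_threshold": self.confidence_threshold,
                "tabu_list_size": self.tabu_list_size,
                "max_nonimproving": self.max_nonimproving,
                "correlation_thresholds": self.correlation_thresholds,
                "correlation_network_subsets": self.correlation_network_subsets,
                "seed": self.seed,
            },
            indent=1,
            sort_keys=True,
        )


def load_feature_table(path, subset: list[str], metadata_path=None) -> pd.DataFrame:
    """Read a feature CSV, select subset columns, drop incomplete rows.

    Rows with missing values in any subset column are dropped with a logged
    warning; duplicate cell ids and non-numeric cells are errors.
    """
    df = pd.read_csv(path)
    if "cell_id" in df.columns:
        if df["cell_id"].duplicated().any():
            raise ValueError(f"{path}: duplicate cell_id rows")
        df = df.set_index("cell_id")
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path).set_index("cell_id")
        df = df.join(meta, how="left", rsuffix="_meta")
    missing_cols = [c for c in subset if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing subset columns {missing_cols}")
    out = df[list(subset)].copy()
    for col in out.columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        newly_bad = coerced.isna() & out[col].notna()
        if newly_bad.any():
            row = out.index[newly_bad][0]
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        out[col] = coerced
    n_before = len(out)
    out = out.dropna()
    if len(out) < n_before:
        logger.warning(
            "%s: dropped %d row(s) with missing subset values", path, n_before - len(out)
        )
    if out.empty:
        raise ValueError(f"{path}: no complete rows left for subset")
    return out.astype(float)


def _group_table(name: str, spec: dict, config: RunConfig) -> pd.DataFrame:
    if "table" in spec:
        all_cols = sorted({c for cols in config.subsets.values() for c in cols})
        return load_feature_table(spec["table"], all_cols, spec.get("metadata"))
    if "synthetic" in spec:
        s = spec["synthetic"]
        scenario = make_confidence_scenario(
            int(s["n"]), int(s["N"]),
            int(s.get("scenario_seed", substream_seed(config.seed, "scenario", name))),
        )
        return scenario.data()
    raise ValueError(f"group {name!r}: need 'table' or 'synthetic'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: RunConfig) -> dict:
    """Execute the full design; returns the manifest (also written to disk)."""
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(config.to_json()), "seeds": {}, "artifacts": {}}

    def emit(relpath: str, text: str) -> None:
        p = out_root / relpath
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(text)
        manifest["artifacts"][relpath] = _sha256(p)

    current_stage = "setup"
    try:
        tables = {
            name: _group_table(name, spec, config)
            for name, spec in config.groups.items()
        }
        models: dict[tuple[str, str], dict] = {}
        for gname, table in tables.items():
            for sname, cols in config.subsets.items():
                current_stage = f"learn[{gname}/{sname}]"
                sub = table[list(cols)]
                z = standardize(sub)
                seed = substream_seed(config.seed, "bootstrap", gname, sname)
                manifest["seeds"][f"{gname}/{sname}"] = seed
                search = SearchConfig(
                    config.tabu_list_size, config.max_nonimproving, frozenset(), seed
                )
                logger.info("%s: bootstrap B=%d", current_stage, config.bootstrap_replicates)
                structures = bootstrap_networks(
                    z, config.bootstrap_replicates, seed, search, pre_standardized=True
                )
                conf = arc_confidence(structures, seed)
                blacklist = build_blacklist(conf, config.confidence_threshold)
                final = tabu_search(
                    z,
                    SearchConfig(
                        config.tabu_list_size, config.max_nonimproving, blacklist, seed
                    ),
                )
                bn = fit_parameters(final, z)
                omega = precision_matrix(bn)
                pcor = partial_correlations(omega)
                cpdag = dag_to_cpdag(final)
                models[(gname, sname)] = {"bn": bn, "data": z, "cpdag": cpdag}

                base = f"{gname}/{sname}"
                emit(
                    f"{base}/confidence.csv",
                    conf.to_dataframe(config.confidence_threshold).to_csv(index=False),
                )
                emit(
                    f"{base}/blacklist.csv",
                    "\n".join(",".join(sorted(p)) for p in sorted(map(sorted, blacklist)))
                    + "\n",
                )
                emit(
                    f"{base}/arcs.csv",
                    "parent,child\n"
                    + "".join(f"{p},{c}\n" for p, c in final.arc_list()),
                )
                emit(f"{base}/structure.dot", final.to_dot())
                emit(f"{base}/parameters.json", bn.to_json())
                emit(f"{base}/cpdag.json", cpdag.to_json())
                names = list(bn.variables)
                import numpy as _np

                emit(
                    f"{base}/omega.csv",
                    pd.DataFrame(_np.asarray(omega), index=names, columns=names).to_csv(),
                )
                emit(
                    f"{base}/partial_correlations.csv",
                    pd.DataFrame(pcor, index=names, columns=names).to_csv(),
                )

        gnames = list(config.groups)
        if len(gnames) == 2:
            ga, gb = gnames
            for sname in config.subsets:
                current_stage = f"compare[{sname}]"
                report = compare_networks(
                    models[(ga, sname)]["bn"],
                    models[(gb, sname)]["bn"],
                    models[(ga, sname)]["data"],
                    models[(gb, sname)]["data"],
                )
                emit(f"comparison_{sname}.json", report.to_json())
            current_stage = "t_table"
            cols = sorted({c for cc in config.subsets.values() for c in cc})
            emit(
                "welch_t_table.csv",
                welch_t_table(tables[ga][cols], tables[gb][cols]).to_csv(),
            )
        for sname in config.correlation_network_subsets:
            for gname in gnames:
                current_stage = f"correlation_network[{gname}/{sname}]"
                tau = config.correlation_thresholds.get(gname, 0.4)
                net = correlation_network(
                    tables[gname][list(config.subsets[sname])], tau
                )
                path = out_root / f"{gname}/{sname}/correlation_network.graphml"
                path.parent.mkdir(parents=True, exist_ok=True)
                net.write_graphml(path)
                manifest["artifacts"][f"{gname}/{sname}/correlation_network.graphml"] = _sha256(path)
    except Exception as exc:
        (out_root / "FAILED").write_text(f"{current_stage}: {exc}\n")
        raise StageError(f"{current_stage}: {exc}") from exc

    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
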