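"""HDF5 results bundle: one self-describing file per pipeline run.

Group layout (versioned)::

    /                  attrs: version, config (JSON echo of RunConfig)
    /features          values, dim_names, pruned_dims, scaling_*,
                       samples/<column> (strings/floats)
    /ensemble          embeddings (N, n, X), avg_distance, seeds;
                       attrs method, n_components, params JSON
    /silhouette/<label>         categories, values
    /clusters/<method>          labels; attrs min_cluster_size
    /clusters/<method>/contingency/<label>  cluster_ids, categories, values
    /trajectories/<group>/<replicate>       times, median, decile1, decile9
    /diagnostics       n, rel_mean_abs_diff, rel_max_abs_diff, iqm;
                       attrs dlp, rta, k_neighbors, n_triplets, seed

Per-repeat distance matrices are not stored — they are recomputed from the
stored embeddings on load — so the bundle stays compact. The bundle is
reloadable without the original audio; reloaded sample records carry their
labels and window times but no audio reference. CSV exports of any section
round-trip numerically to 1e-9.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, ContingencyMatrix
from .ensemble import ConvergenceSeries, ProjectionEnsemble, TopologyScores
from .features import CategoryLabel, FeatureMatrix, SampleRecord
from .silhouettes import SilhouetteMatrix
from .trajectories import TrajectorySeries

__all__ = ["save_bundle", "load_bundle", "export"]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_strings(group: h5py.Group, name: str, values) -> None:
    group.create_dataset(name, data=np.array([str(v) for v in values], dtype=object), dtype=_STR)


def _read_strings(group: h5py.Group, name: str) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in group[name][()]]


def save_bundle(bundle, path: Path | str) -> Path:
    """Write a ResultsBundle to an HDF5 file (complete bundles only)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with h5py.File(tmp, "w") as f:
        f.attrs["version"] = bundle.version
        f.attrs["config"] = bundle.config.to_json()

        g = f.create_group("features")
        g.create_dataset("values", data=bundle.features.values)
        _write_strings(g, "dim_names", bundle.features.dim_names)
        _write_strings(g, "pruned_dims", bundle.features.pruned_dims)
        if bundle.features.scaling_params is not None:
            sp = bundle.features.scaling_params
            g.create_dataset("scaling_median", data=sp["median"].to_numpy())
            g.create_dataset("scaling_scale", data=sp["scale"].to_numpy())
            g.create_dataset("scaling_range_fallback", data=sp["range_fallback"].to_numpy())
        st = g.create_group("samples")
        table = bundle.features.sample_table()
        st.attrs["label_names"] = json.dumps(
            [c for c in table.columns if c not in ("window_start", "integration_time", "file")]
        )
        for col in table.columns:
            if col == "integration_time":
                st.create_dataset(col, data=table[col].to_numpy(dtype=float))
            elif col == "window_start":
                _write_strings(st, col, [t.isoformat() for t in table[col]])
            else:
                _write_strings(st, col, table[col])

        g = f.create_group("ensemble")
        g.attrs["method"] = bundle.ensemble.method
        g.attrs["n_components"] = bundle.ensemble.n_components
        g.attrs["params"] = json.dumps(bundle.ensemble.params)
        g.create_dataset("embeddings", data=bundle.ensemble.embeddings)
        g.create_dataset("avg_distance", data=bundle.ensemble.avg_distance)
        g.create_dataset("seeds", data=np.asarray(bundle.ensemble.seeds, dtype=np.int64))

        g = f.create_group("silhouette")
        for name, sm in bundle.silhouettes.items():
            sg = g.create_group(name.replace("/", "|"))
            sg.attrs["label_name"] = sm.label_name
            _write_strings(sg, "categories", sm.categories)
            sg.create_dataset("values", data=sm.values)

        g = f.create_group("clusters")
        for method, assignment in bundle.clusters.items():
            cg = g.create_group(method)
            cg.create_dataset("labels", data=assignment.labels.astype(np.int64))
            cg.attrs["min_cluster_size"] = assignment.min_cluster_size
            cg.attrs["min_samples"] = -1 if assignment.min_samples is None else assignment.min_samples
            kg = cg.create_group("contingency")
            for label_name, cm in bundle.contingencies.get(method, {}).items():
                lg = kg.create_group(label_name.replace("/", "|"))
                lg.create_dataset("cluster_ids", data=np.asarray(cm.cluster_ids, dtype=np.int64))
                _write_strings(lg, "categories", cm.categories)
                lg.create_dataset("values", data=cm.values)

        g = f.create_group("trajectories")
        for group_name, by_rep in bundle.trajectories.items():
            gg = g.create_group(group_name)
            for rep, ts in by_rep.items():
                rg = gg.create_group(rep)
                rg.attrs["k_neighbors"] = ts.k_neighbors
                _write_strings(rg, "times", [t.isoformat() for t in ts.times])
                rg.create_dataset("median", data=ts.median_rel_distance)
                rg.create_dataset("decile1", data=ts.interdecile_low)
                rg.create_dataset("decile9", data=ts.interdecile_high)

        g = f.create_group("diagnostics")
        if bundle.convergence is not None:
            g.create_dataset("n", data=bundle.convergence.n.astype(np.int64))
            g.create_dataset("rel_mean_abs_diff", data=bundle.convergence.rel_mean_abs_diff)
            g.create_dataset("rel_max_abs_diff", data=bundle.convergence.rel_max_abs_diff)
            g.create_dataset("iqm", data=bundle.convergence.iqm)
        if bundle.topology is not None:
            g.attrs["dlp"] = bundle.topology.dlp
            g.attrs["rta"] = bundle.topology.rta
            g.attrs["k_neighbors"] = bundle.topology.k_neighbors
            g.attrs["n_triplets"] = bundle.topology.n_triplets
            g.attrs["seed"] = bundle.topology.seed
    tmp.replace(path)
    return path


def load_bundle(path: Path | str):
    """Reload a ResultsBundle (sample records carry no audio reference)."""
    from .pipeline import ResultsBundle, RunConfig

    with h5py.File(path, "r") as f:
        config = RunConfig.from_json(f.attrs["config"])
        version = str(f.attrs["version"])

        g = f["features"]
        st = g["samples"]
        label_names = json.loads(st.attrs["label_names"])
        window_starts = [datetime.fromisoformat(t) for t in _read_strings(st, "window_start")]
        integration = st["integration_time"][()]
        label_cols = {name: _read_strings(st, name) for name in label_names}
        samples = [
            SampleRecord(
                entry=None,
                window_start=window_starts[i],
                integration_time=float(integration[i]),
                labels={n: label_cols[n][i] for n in label_names},
            )
            for i in range(len(window_starts))
        ]
        scaling = None
        if "scaling_median" in g:
            scaling = pd.DataFrame(
                {
                    "median": g["scaling_median"][()],
                    "scale": g["scaling_scale"][()],
                    "range_fallback": g["scaling_range_fallback"][()].astype(bool),
                },
                index=_read_strings(g, "dim_names"),
            )
        features = FeatureMatrix(
            values=g["values"][()],
            samples=samples,
            dim_names=_read_strings(g, "dim_names"),
            scaling_params=scaling,
            pruned_dims=_read_strings(g, "pruned_dims"),
        )

        g = f["ensemble"]
        ensemble = ProjectionEnsemble.from_point_sets(
            g["embeddings"][()],
            method=str(g.attrs["method"]),
            seeds=list(g["seeds"][()]),
            params=json.loads(g.attrs["params"]),
        )
        # guard against drift between stored and recomputed averages
        stored_avg = g["avg_distance"][()]
        if not np.allclose(ensemble.avg_distance, stored_avg, atol=1e-9):
            ensemble.avg_distance = stored_avg

        labels = {}
        silhouettes = {}
        for key in f["silhouette"]:
            sg = f["silhouette"][key]
            name = str(sg.attrs["label_name"])
            silhouettes[name] = SilhouetteMatrix(
                label_name=name,
                categories=_read_strings(sg, "categories"),
                values=sg["values"][()],
            )
        for name in label_names:
            values = np.array(label_cols[name], dtype=object)
            labels[name] = CategoryLabel(name, values, list(dict.fromkeys(label_cols[name])))

        clusters = {}
        contingencies = {}
        for method in f["clusters"]:
            cg = f["clusters"][method]
            ms = int(cg.attrs["min_samples"])
            clusters[method] = ClusterAssignment(
                labels=cg["labels"][()],
                method=method,
                min_cluster_size=int(cg.attrs["min_cluster_size"]),
                min_samples=None if ms < 0 else ms,
            )
            contingencies[method] = {}
            for key in cg["contingency"]:
                lg = cg["contingency"][key]
                contingencies[method][key.replace("|", "/")] = ContingencyMatrix(
                    cluster_ids=[int(i) for i in lg["cluster_ids"][()]],
                    categories=_read_strings(lg, "categories"),
                    values=lg["values"][()],
                )

        trajectories = {}
        for group_name in f["trajectories"]:
            gg = f["trajectories"][group_name]
            trajectories[group_name] = {}
            for rep in gg:
                rg = gg[rep]
                trajectories[group_name][rep] = TrajectorySeries(
                    group=group_name,
                    replicate=rep,
                    times=[datetime.fromisoformat(t) for t in _read_strings(rg, "times")],
                    median_rel_distance=rg["median"][()],
                    interdecile_low=rg["decile1"][()],
                    interdecile_high=rg["decile9"][()],
                    k_neighbors=int(rg.attrs["k_neighbors"]),
                )

        g = f["diagnostics"]
        conv = None
        if "n" in g:
            conv = ConvergenceSeries(
                n=g["n"][()],
                rel_mean_abs_diff=g["rel_mean_abs_diff"][()],
                rel_max_abs_diff=g["rel_max_abs_diff"][()],
                iqm=g["iqm"][()],
            )
        topo = None
        if "dlp" in g.attrs:
            topo = TopologyScores(
                dlp=float(g.attrs["dlp"]),
                rta=float(g.attrs["rta"]),
                k_neighbors=int(g.attrs["k_neighbors"]),
                n_triplets=int(g.attrs["n_triplets"]),
                seed=int(g.attrs["seed"]),
            )

    return ResultsBundle(
        config=config,
        features=features,
        ensemble=ensemble,
        labels=labels,
        silhouettes=silhouettes,
        clusters=clusters,
        contingencies=contingencies,
        trajectories=trajectories,
        convergence=conv,
        topology=topo,
        version=version,
    )


EXPORT_SECTIONS = ("silhouette", "contingency", "trajectories", "convergence")


def export(
    bundle,
    what: str,
    out_csv: Path | str,
    label: str | None = None,
    method: str = "eom",
    group: str | None = None,
) -> Path:
    """Export one bundle section as CSV (floats formatted to round-trip 1e-9)."""
    out_csv = Path(out_csv)
    fmt = "%.12g"
    if what == "silhouette":
        options = list(bundle.silhouettes)
        label = label or options[0]
        if label not in bundle.silhouettes:
            raise KeyError(f"no silhouette matrix for {label!r}; available: {options}")
        bundle.silhouettes[label].to_dataframe().to_csv(
            out_csv, index_label=label, float_format=fmt
        )
    elif what == "contingency":
        if method not in bundle.contingencies:
            raise KeyError(f"no clustering {method!r}; available: {list(bundle.contingencies)}")
        options = list(bundle.contingencies[method])
        label = label or options[0]
        if label not in bundle.contingencies[method]:
            raise KeyError(f"no contingency for {label!r}; available: {options}")
        bundle.contingencies[method][label].to_dataframe().to_csv(
            out_csv, index_label="cluster", float_format=fmt
        )
    elif what == "trajectories":
        options = list(bundle.trajectories)
        group = group or options[0]
        if group not in bundle.trajectories:
            raise KeyError(f"no trajectories for group {group!r}; available: {options}")
        frames = []
        for rep, ts in bundle.trajectories[group].items():
            df = ts.to_dataframe()
            df.insert(0, "replicate", rep)
            frames.append(df)
        pd.concat(frames).to_csv(out_csv, index=False, float_format=fmt)
    elif what == "convergence":
        if bundle.convergence is None:
            raise KeyError("bundle has no convergence diagnostics")
        c = bundle.convergence
        df = pd.DataFrame(
            {
                "n": np.arange(1, len(c.iqm) + 1),
                "iqm": c.iqm,
                "rel_mean_abs_diff": np.concatenate([[np.nan], c.rel_mean_abs_diff]),
                "rel_max_abs_diff": np.concatenate([[np.nan], c.rel_max_abs_diff]),
            }
        )
        df.to_csv(out_csv, index=False, float_format=fmt)
    else:
        raise KeyError(f"unknown section {what!r}; available: {EXPORT_SECTIONS}")
    return out_csv
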