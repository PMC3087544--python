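"""End-to-end orchestration: filter -> distances -> metrics -> rank tests ->
identification -> combination -> contaminant screen.

Every stage emits plain TSV/JSON so each artifact can be validated against
independent oracles; a provenance record (config, seed, package version) is
written alongside.  Stage failures abort with the failing stage named;
artifacts already written are left in place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from io import StringIO
from itertools import combinations
from pathlib import Path
from typing import Any

import yaml

import barcodekit
from barcodekit import divergence, identify, k2p, ranktest, screen as screen_mod, simulate, taxa
from barcodekit.align import ScoringScheme

__all__ = ["RunConfig", "PipelineError", "run_full_evaluation"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative run description (YAML/JSON serialisable).

    Either ``marker_fastas`` (marker -> path) or ``simulation`` must be
    given.  ``simulation`` holds base simulator fields plus an optional
    ``per_marker`` mapping of field overrides; all simulated markers share
    one taxonomy layout, so samples correspond across markers.
    """

    outdir: str = "barcodekit-run"
    seed: int = 0
    marker_fastas: dict[str, str] = field(default_factory=dict)
    simulation: dict[str, Any] = field(default_factory=dict)
    header_scheme: str = "pipe"
    min_len: int = 100
    max_ambig: int = 15
    drop_unnamed: bool = True
    alignment_mode: str = "pairwise-global"
    identification_mode: str = "self-inclusive"
    wilcoxon_method: str = "normal-approx"
    scoring: dict[str, float] = field(default_factory=dict)
    screen: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(**self.scoring) if self.scoring else ScoringScheme()

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _load_datasets(config: RunConfig) -> dict[str, taxa.BarcodeDataset]:
    datasets: dict[str, taxa.BarcodeDataset] = {}
    if config.marker_fastas:
        for marker, path in config.marker_fastas.items():
            records = taxa.parse_fasta(path, marker=marker, header_scheme=config.header_scheme)
            datasets[marker] = taxa.BarcodeDataset(marker=marker, records=records)
    if config.simulation:
        sim = dict(config.simulation)
        per_marker = sim.pop("per_marker", {"SIM-A": {}, "SIM-B": {}})
        sim.setdefault("seed", config.seed)
        for marker, overrides in per_marker.items():
            cfg = simulate.SimConfig(marker=marker, **{**sim, **overrides})
            records, _ = simulate.simulate_dataset(cfg)
            datasets[marker] = taxa.BarcodeDataset(marker=marker, records=records)
    if not datasets:
        raise ValueError("config provides neither marker inputs nor a simulation")
    return datasets


def _sample_of(marker: str, record_id: str) -> str:
    prefix = f"{marker}-"
    return record_id[len(prefix):] if record_id.startswith(prefix) else record_id


def run_full_evaluation(config: RunConfig) -> dict[str, str]:
    """Run every computational stage and return {artifact name: path}."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        artifacts[name] = str(path)

    datasets = _stage("load")(_load_datasets)(config)
    scheme = config.scheme()

    # Stage: quality filter + dataset summaries.
    @_stage("filter")
    def do_filter():
        filtered: dict[str, taxa.BarcodeDataset] = {}
        summary_rows = []
        for marker, ds in datasets.items():
            kept, report = taxa.quality_filter(
                ds.records, config.min_len, config.max_ambig, config.drop_unnamed
            )
            emit(f"filter_report_{marker}.tsv", report.to_tsv())
            filtered[marker] = taxa.BarcodeDataset(marker=marker, records=kept)
            s = taxa.dataset_summary(filtered[marker]).to_dict()
            summary_rows.append({"marker": marker, **s})
        header = list(summary_rows[0])
        lines = ["\t".join(header)] + [
            "\t".join(str(r[h]) for h in header) for r in summary_rows
        ]
        emit("dataset_summary.tsv", "\n".join(lines) + "\n")
        return filtered

    filtered = do_filter()

    # Stage: optional contaminant screen (applied before analysis).
    if config.screen:
        @_stage("screen")
        def do_screen():
            sc = dict(config.screen)
            threshold = sc.get("threshold_bits")  # None -> calibrated cutoff
            if threshold is not None:
                threshold = float(threshold)
            training_path = sc.get("training_fasta")
            if training_path:
                training = taxa.parse_fasta(
                    training_path, marker="training", header_scheme=config.header_scheme
                )
            else:
                raise ValueError("screen config requires training_fasta")
            hmm = screen_mod.build_profile_hmm(
                training,
                gap_column_threshold=float(sc.get("gap_column_threshold", 0.5)),
                pseudocount=float(sc.get("pseudocount", 1.0)),
            )
            for marker in sc.get("markers", list(filtered)):
                result = screen_mod.screen(filtered[marker].records, hmm, threshold)
                result_io = StringIO()
                result.to_tsv(result_io)
                emit(f"screen_{marker}.tsv", result_io.getvalue())
                filtered[marker] = taxa.BarcodeDataset(
                    marker=marker, records=list(result.kept)
                )
        do_screen()

    # Stage: distance matrices.
    @_stage("distances")
    def do_distances():
        matrices = {}
        for marker, ds in filtered.items():
            m = k2p.distance_matrix(ds, mode=config.alignment_mode, scheme=scheme)
            path = outdir / f"distance_matrix_{marker}.tsv"
            m.to_tsv(path)
            artifacts[path.name] = str(path)
            matrices[marker] = m
        return matrices

    matrices = do_distances()

    # Stage: divergence metrics.
    @_stage("metrics")
    def do_metrics():
        per_marker = {}
        for marker, ds in filtered.items():
            intra = divergence.intraspecific_metrics(matrices[marker], ds)
            inter = divergence.interspecific_metrics(matrices[marker], ds)
            per_marker[marker] = (intra, inter)
            lines = ["genus\tmean\tmin\tn_pairs"] + [
                f"{g}\t{m:.6g}\t{mn:.6g}\t{np_}"
                for g, (m, mn, np_) in sorted(inter.per_genus.items())
            ]
            emit(f"per_genus_inter_{marker}.tsv", "\n".join(lines) + "\n")
        table = divergence.divergence_table(per_marker)
        emit("divergence_table.tsv", table.to_csv(sep="\t", index=False))
        return per_marker

    per_marker_metrics = do_metrics()

    # Stage: pairwise Wilcoxon signed-rank tests.
    if len(filtered) >= 2:
        @_stage("wilcoxon")
        def do_wilcoxon():
            inter_by_marker = {m: v[1] for m, v in per_marker_metrics.items()}
            table = ranktest.pairwise_marker_tests(
                inter_by_marker, method=config.wilcoxon_method
            )
            emit("wilcoxon_table.tsv", table.to_csv(sep="\t", index=False))
        do_wilcoxon()

    # Stage: identification (both methods) + per-genus rates.
    @_stage("identify")
    def do_identify():
        reports = {}
        rows = []
        for marker, ds in filtered.items():
            for method in ("blast1", "distance"):
                rep = identify.evaluate_identification(
                    ds,
                    method=method,
                    mode=config.identification_mode,
                    scheme=scheme,
                    matrix=matrices[marker] if method == "distance" else None,
                )
                reports[(marker, method)] = rep
                rows.append(
                    {
                        "marker": marker,
                        "method": method,
                        "mode": rep.mode,
                        "n_queries": rep.n_queries,
                        "species_rate": f"{rep.species_rate:.1f}",
                        "genus_rate": f"{rep.genus_rate:.1f}",
                    }
                )
                glines = ["genus\tn\tspecies_rate\tgenus_rate"] + [
                    f"{g}\t{n}\t{sr:.1f}\t{gr:.1f}"
                    for g, (n, sr, gr) in rep.per_genus_rates.items()
                ]
                emit(f"identification_per_genus_{marker}_{method}.tsv", "\n".join(glines) + "\n")
                emit(
                    f"assignments_{marker}_{method}.json",
                    json.dumps(
                        [
                            {
                                "query_id": a.query_id,
                                "assigned_species": a.assigned_species,
                                "best_refs": sorted(a.best_refs),
                                "species_correct": a.species_correct,
                                "genus_correct": a.genus_correct,
                            }
                            for a in rep.assignments
                        ],
                        indent=1,
                    ),
                )
        header = list(rows[0])
        lines = ["\t".join(header)] + ["\t".join(str(r[h]) for h in header) for r in rows]
        emit("identification_summary.tsv", "\n".join(lines) + "\n")
        return reports

    id_reports = do_identify()

    # Stage: traffic-light combinations over marker pairs (per method).
    if len(filtered) >= 2:
        @_stage("combine")
        def do_combine():
            sample_map: dict[str, dict[str, str]] = {}
            for marker, ds in filtered.items():
                for rid in ds.record_ids:
                    sample_map.setdefault(_sample_of(marker, rid), {})[marker] = rid
            rows = []
            for method in ("blast1", "distance"):
                for ma, mb in combinations(sorted(filtered), 2):
                    try:
                        comb = identify.combine_markers(
                            [id_reports[(ma, method)], id_reports[(mb, method)]],
                            sample_map,
                        )
                    except ValueError:
                        continue  # no shared samples for this pair
                    rows.append(
                        {
                            "combination": "+".join(comb.member_markers),
                            "method": method,
                            "n_common_samples": comb.n_common_samples,
                            "species_rate": f"{comb.species_rate:.1f}",
                            "genus_rate": f"{comb.genus_rate:.1f}",
                        }
                    )
            if rows:
                header = list(rows[0])
                lines = ["\t".join(header)] + [
                    "\t".join(str(r[h]) for h in header) for r in rows
                ]
                emit("combination.tsv", "\n".join(lines) + "\n")
        do_combine()

    # Provenance.
    emit(
        "provenance.json",
        json.dumps(
            {
                "package": "barcodekit",
                "version": barcodekit.__version__,
                "config": dataclasses.asdict(config),
                "config_digest": config.digest(),
                "seed": config.seed,
                "decisions": {
                    "alignment_mode": config.alignment_mode,
                    "identification_mode": config.identification_mode,
                    "tie_rule": "ties are failures",
                    "wilcoxon": f"{config.wilcoxon_method}, two-sided, no continuity correction",
                },
            },
            indent=1,
        ),
    )
    return artifacts
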