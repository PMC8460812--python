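"""End-to-end synthetic plasmid-stability experiment driver.

Reproduces the logic of the wet-lab design on simulated data: sequence a bulk
broth culture, estimate chromosome-normalized copy number of every plasmid,
pick n clonal colonies from a plate seeded with the same culture, sequence
each colony, score plasmid presence/absence, and test polyploidy against
unstable inheritance.  Deterministic for a fixed seed; every output file
carries a provenance header (package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .coverage import normcov_tracks, summarize_copy_numbers, windowed_depth
from .population import ColonyPanel, PopulationModel, sample_panel
from .readsim import ReadPairSpec, simulate_reads
from .replicons import GenomeModel, Replicon, msh1_registry, random_replicon
from .stability import epsilon_sensitivity, test_panel

__all__ = ["RunConfig", "attach_random_sequences", "run_experiment"]


@dataclass
class RunConfig:
    """Configuration of one synthetic stability experiment."""

    seed: int = 1
    ploidy: float = 2.0
    plasmid_copy: dict[str, float] = field(default_factory=dict)
    carriage: dict[str, float] = field(default_factory=dict)
    epsilon: float = 0.02  # background colony loss rate under polyploidy
    alpha: float = 0.05
    n_colonies: int = 14
    n_pairs_bulk: int = 100_000
    n_pairs_colony: int = 5_000
    window_bp: int = 1000
    read_length: int = 151
    fragment_mean: int = 400
    fragment_sd: int = 40
    substitution_rate: float = 0.0
    presence_normcov_min: float = 0.05  # colony presence call threshold
    genome_scale: float = 1.0  # shrink registry lengths for quick runs

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def attach_random_sequences(
    registry: GenomeModel, seed: int, scale: float = 1.0
) -> GenomeModel:
    """Random sequences at each registry replicon's printed length and GC.

    ``scale`` < 1 shrinks every replicon proportionally (minimum 2 kb) for
    quick desk-scale runs; lengths and GC stay the registry values at
    scale = 1.
    """
    rng = np.random.default_rng(seed)
    replicons = []
    for rep in registry:
        length = max(2000, int(round(rep.length_bp * scale)))
        gc = (rep.gc_percent or 60.0) / 100.0
        replicons.append(
            Replicon.from_sequence(
                rep.name,
                random_replicon(rep.name, length, gc, rng=rng).sequence,
                role=rep.role,
            )
        )
    return GenomeModel(replicons)


def _provenance(config: RunConfig) -> str:
    return f"# normcov v{__version__} seed={config.seed} config={config.digest()}\n"


def _write_tsv(df: pd.DataFrame, path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False)


def _colony_presence(
    model: PopulationModel,
    founder,
    spec: ReadPairSpec,
    config: RunConfig,
) -> dict[str, bool]:
    """Call plasmid presence in one sequenced colony from its NormCov."""
    aln = simulate_reads(model, spec, founder=founder)
    tracks = windowed_depth(aln, window_bp=config.window_bp)
    nc = normcov_tracks(tracks, model.genome.chromosome.name)
    out = {}
    for p in model.genome.plasmids:
        track = nc[p.name].values
        widths = (track["end"] - track["start"]).to_numpy(float)
        mean = float(np.average(track["normcov"].to_numpy(float), weights=widths))
        out[p.name] = mean >= config.presence_normcov_min
    return out


def run_experiment(config: RunConfig, outdir) -> dict:
    """Run the full simulate → coverage → NormCov → colony-test pipeline.

    Writes ``copy_number.tsv``, ``colony_panel.tsv``, ``stability.tsv``,
    ``epsilon_sensitivity.tsv`` and ``verdicts.json`` under ``outdir`` and
    returns the result dictionary.  Stage failures abort with a stage-tagged
    message.
    """
    os.makedirs(outdir, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(4)]

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"[{name}] {exc}") from exc

    # --- genome & population -------------------------------------------
    def _build():
        genome = attach_random_sequences(
            msh1_registry(), seeds[0], scale=config.genome_scale
        )
        model = PopulationModel(
            genome=genome,
            ploidy=config.ploidy,
            plasmid_copy=config.plasmid_copy,
            carriage=config.carriage,
        )
        return genome, model

    genome, model = _stage("population", _build)

    # --- bulk sequencing + copy number ---------------------------------
    def _bulk():
        spec = ReadPairSpec(
            n_pairs=config.n_pairs_bulk,
            read_length=config.read_length,
            fragment_mean=config.fragment_mean,
            fragment_sd=config.fragment_sd,
            substitution_rate=config.substitution_rate,
            seed=seeds[1],
        )
        aln = simulate_reads(model, spec)
        tracks = windowed_depth(aln, window_bp=config.window_bp)
        nc = normcov_tracks(tracks, genome.chromosome.name)
        return summarize_copy_numbers(nc, seed=seeds[1])

    summary = _stage("coverage", _bulk)
    _write_tsv(summary, os.path.join(outdir, "copy_number.tsv"), config)

    # --- colony panel ---------------------------------------------------
    def _panel():
        # colonies are founded by cells of the same population; under
        # polyploidy (carriage 1) a small background loss rate epsilon applies
        carriage = {
            p.name: min(model.carriage[p.name], 1.0 - config.epsilon)
            for p in genome.plasmids
        }
        panel_model = PopulationModel(
            genome=genome,
            ploidy=config.ploidy,
            plasmid_copy=config.plasmid_copy,
            carriage=carriage,
        )
        rng = np.random.default_rng(seeds[2])
        truth = sample_panel(panel_model, config.n_colonies, rng=rng)
        if config.n_pairs_colony > 0:
            spec_base = ReadPairSpec(
                n_pairs=config.n_pairs_colony,
                read_length=config.read_length,
                fragment_mean=config.fragment_mean,
                fragment_sd=config.fragment_sd,
                substitution_rate=config.substitution_rate,
                seed=0,
            )
            from dataclasses import replace

            founders = []
            for i, f in enumerate(truth.founders):
                spec = replace(spec_base, seed=int(rng.integers(2**31 - 1)))
                presence = _colony_presence(panel_model, f, spec, config)
                founders.append(type(f)(presence=presence, ploidy=f.ploidy))
            losses = {
                p.name: sum(not f.presence[p.name] for f in founders)
                for p in genome.plasmids
            }
            return ColonyPanel(
                n=config.n_colonies, losses=losses, founders=founders
            )
        return truth

    panel = _stage("colonies", _panel)
    panel_df = panel.to_frame()
    _write_tsv(panel_df, os.path.join(outdir, "colony_panel.tsv"), config)

    # --- stability inference -------------------------------------------
    def _test():
        bulk = {
            row["replicon"]: row["normcov_mean"]
            for _, row in summary.iterrows()
            if row["replicon"] != genome.chromosome.name
        }
        return test_panel(
            bulk, panel, epsilon=config.epsilon, alpha=config.alpha
        )

    stability = _stage("stability", _test)
    _write_tsv(stability, os.path.join(outdir, "stability.tsv"), config)

    sens_frames = []
    for _, row in stability.iterrows():
        sens = epsilon_sensitivity(row["c_hat"], panel, row["plasmid"])
        sens.insert(0, "plasmid", row["plasmid"])
        sens_frames.append(sens)
    _write_tsv(
        pd.concat(sens_frames, ignore_index=True),
        os.path.join(outdir, "epsilon_sensitivity.tsv"),
        config,
    )

    verdicts = {
        row["plasmid"]: row["verdict"] for _, row in stability.iterrows()
    }
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": config.digest(),
        "mu_normcov": {
            row["replicon"]: row["normcov_mean"] for _, row in summary.iterrows()
        },
        "losses": dict(panel.losses),
        "verdicts": verdicts,
    }
    with open(os.path.join(outdir, "verdicts.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
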