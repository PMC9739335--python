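"""End-to-end orchestration: simulate -> SDM -> overlap -> barriers ->
cascade -> association.

`run_pipeline` executes the stages in barrier order on a synthetic scenario,
writes every intermediate product as a text file, and returns a
:class:`RunManifest` recording the configuration hash, seeds, and per-file
checksums so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import datetime
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .assoc import parse_newick, ri_distance_report
from .barriers import assemble_barriers, barriers_to_frame
from .cascade import (
    build_ri_table,
    cascades_to_frame,
    compose,
    relative_contributions,
)
from .config import ScenarioConfig, default_scenario
from .io import (
    write_crosses, write_env_grid, write_flowering, write_json,
    write_matrix, write_newick_file, write_occurrences, write_surface,
)
from .overlap import d_matrix, normalize_surface, phenology_distribution
from .sdm import fit_sdm, generate_pseudo_absences, predict_surface, relative_intensity
from .synth import (
    make_environment, simulate_crosses, simulate_flowering,
    simulate_occurrences, simulate_tree,
)

log = logging.getLogger("ricascade")


@dataclass
class PipelineConfig:
    """All stage parameters for one pipeline run.

    Defaults follow the study protocol where one is stated: 0.05-degree
    pseudo-absence buffer, 4:1 absence ratio, 70/30 train/test split, 7-day
    phenology bins, and exclusion of cross cells with fewer than 5 records.
    """

    scenario: ScenarioConfig = field(default_factory=default_scenario)
    out_dir: str | Path = "ricascade_run"
    buffer_deg: float = 0.05
    absence_ratio: int = 4
    train_fraction: float = 0.7
    week_length_days: int = 7
    trim_quantile: float = 0.0
    min_n: int = 5
    pool_donors: bool = True
    n_permutations: int = 9999
    mantel_symmetrize: str = "mean"
    #: scale on which eco-geographic overlap is computed: the model's relative
    #: occurrence intensity (consistent for distributions over sites) or the
    #: raw predicted probability
    eco_overlap_scale: str = "intensity"  # intensity | probability
    # synthetic sampling design
    n_flowering_garden: int = 40
    n_flowering_wild: int = 60
    acceptors: list[str] | None = None  # None = every species
    n_within_pollinations: int = 30
    n_between_pollinations: int = 12
    # stage toggles
    include_crosses: bool = True
    include_association: bool = True


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    rng_seed: int
    version: str
    timestamp: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "rng_seed": self.rng_seed,
            "version": self.version,
            "timestamp": self.timestamp,
            "outputs": self.outputs,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = repr((
        sorted(config.scenario.to_dict().items(), key=str),
        sorted((k, v) for k, v in vars(config).items()
               if k not in ("scenario", "out_dir")),
    ))
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage on the configured synthetic scenario.

    Produces, under ``out_dir``: the simulated inputs (environment layers,
    occurrences, flowering, crosses, tree), per-species SDM surfaces and
    metrics, D matrices (eco-geographic and phenological, garden and wild),
    long-format barrier and cascade tables for both phenology sources, the
    paired total-RI matrix, relative barrier contributions, and the Mantel
    association report.
    """
    sc = config.scenario
    species = sc.species
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    # --- stage: simulate -------------------------------------------------
    log.info("simulate: %d species, seed %d", len(species), sc.rng_seed)
    env = make_environment(sc)
    for p in write_env_grid(out / "env", env):
        emit(p)
    presence_sets = {sp: simulate_occurrences(sc, env, sp) for sp in species}
    flowering = []
    for sp in species:
        flowering += simulate_flowering(sc, sp, config.n_flowering_garden, source="garden")
        flowering += simulate_flowering(sc, sp, config.n_flowering_wild, source="wild")
    from .io import flowering_to_frame
    flowering_df = flowering_to_frame(flowering)

    cross_records = []
    if config.include_crosses:
        acceptors = config.acceptors or species
        for acc in acceptors:
            cross_records.append(
                simulate_crosses(sc, acc, acc, config.n_within_pollinations)
            )
            for don in species:
                if don != acc:
                    cross_records.append(
                        simulate_crosses(sc, acc, don, config.n_between_pollinations)
                    )
    from .io import crosses_to_frame
    crosses_df = crosses_to_frame(cross_records)
    newick = simulate_tree(species, rng_seed=sc.rng_seed)

    write_occurrences(out / "occurrences.csv", list(presence_sets.values()))
    write_flowering(out / "flowering.csv", flowering_df)
    write_crosses(out / "crosses.csv", crosses_df)
    write_newick_file(out / "tree.nwk", newick)
    emit(out / "occurrences.csv"); emit(out / "flowering.csv")
    emit(out / "crosses.csv"); emit(out / "tree.nwk")

    # --- stage: sdm ------------------------------------------------------
    log.info("sdm: buffer %.3f deg, ratio %d:1, split %.0f/%.0f",
             config.buffer_deg, config.absence_ratio,
             100 * config.train_fraction, 100 * (1 - config.train_fraction))
    fits, surfaces = {}, {}
    absence_sets = {}
    for i, sp in enumerate(species):
        absences = generate_pseudo_absences(
            presence_sets[sp], env, buffer_deg=config.buffer_deg,
            ratio=config.absence_ratio, rng_seed=sc.rng_seed * 1000 + i,
        )
        absence_sets[sp] = absences
        fit = fit_sdm(
            presence_sets[sp], absences, env,
            train_fraction=config.train_fraction,
            rng_seed=sc.rng_seed * 1000 + i,
        )
        fits[sp] = fit
        prob = predict_surface(fit, env)
        if config.eco_overlap_scale == "intensity":
            surfaces[sp] = normalize_surface(relative_intensity(fit, env))
        elif config.eco_overlap_scale == "probability":
            surfaces[sp] = normalize_surface(prob)
        else:
            raise ValueError(f"unknown eco_overlap_scale {config.eco_overlap_scale!r}")
        write_surface(out / f"surface_{sp}.asc", prob)
        emit(out / f"surface_{sp}.asc")
        write_surface(out / f"intensity_{sp}.asc", relative_intensity(fit, env))
        emit(out / f"intensity_{sp}.asc")
        log.info("  %s: AUC %.3f, TSS %.3f", sp, fit.auc, fit.tss)
    write_occurrences(out / "pseudo_absences.csv", list(absence_sets.values()))
    emit(out / "pseudo_absences.csv")
    write_json(out / "sdm_fits.json", {
        sp: {
            "intercept": f.intercept, "coefficients": f.coefficients,
            "auc": f.auc, "tss": f.tss, "tss_threshold": f.tss_threshold,
            "train_fraction": f.train_fraction, "rng_seed": f.rng_seed,
        }
        for sp, f in fits.items()
    })
    emit(out / "sdm_fits.json")

    # --- stage: overlap --------------------------------------------------
    d_eco = d_matrix(surfaces, species)
    write_matrix(out / "d_eco.csv", d_eco); emit(out / "d_eco.csv")
    d_phen = {}
    for source in ("garden", "wild"):
        dists = {
            sp: phenology_distribution(
                flowering_df, sp, source,
                week_length_days=config.week_length_days,
                trim_quantile=config.trim_quantile,
            )
            for sp in species
        }
        d_phen[source] = d_matrix(dists, species)
        write_matrix(out / f"d_phenology_{source}.csv", d_phen[source])
        emit(out / f"d_phenology_{source}.csv")

    # --- stage: barriers + cascade ---------------------------------------
    cascades = {}
    for source in ("garden", "wild"):
        series = assemble_barriers(
            d_eco, d_phen[source],
            crosses_df if config.include_crosses else None,
            species, phenology_source=source,
            min_n=config.min_n, pool_donors=config.pool_donors,
        )
        cascades[source] = [compose(s) for s in series]
        barriers_to_frame(series).to_csv(out / f"barriers_{source}.csv", index=False)
        emit(out / f"barriers_{source}.csv")
        cascades_to_frame(cascades[source], series).to_csv(
            out / f"cascades_{source}.csv", index=False
        )
        emit(out / f"cascades_{source}.csv")
        relative_contributions(cascades[source]).to_csv(
            out / f"relative_contributions_{source}.csv", index=False
        )
        emit(out / f"relative_contributions_{source}.csv")

    ri_table = build_ri_table(cascades["garden"], cascades["wild"], species)
    write_matrix(out / "total_ri_matrix.csv", ri_table)
    emit(out / "total_ri_matrix.csv")
    ri_table_2dp = build_ri_table(cascades["garden"], cascades["wild"], species, decimals=2)
    write_matrix(out / "total_ri_matrix_2dp.csv", ri_table_2dp)
    emit(out / "total_ri_matrix_2dp.csv")

    # --- stage: association ----------------------------------------------
    if config.include_association:
        from .cascade import RICascade

        def directed(cascades_list: list[RICascade]):
            import numpy as np
            import pandas as pd
            mat = pd.DataFrame(0.0, index=species, columns=species)
            for c in cascades_list:
                mat.loc[c.acceptor, c.donor] = c.total
            np.fill_diagonal(mat.values, 0.0)
            return mat

        report = ri_distance_report(
            directed(cascades["garden"]), directed(cascades["wild"]),
            parse_newick(newick),
            n_permutations=config.n_permutations,
            rng_seed=sc.rng_seed,
            symmetrize=config.mantel_symmetrize,
        )
        write_json(out / "mantel_report.json", report)
        emit(out / "mantel_report.json")
        log.info("mantel: garden r=%.3f p=%.4f; wild r=%.3f p=%.4f",
                 report["tests"]["garden"]["r"], report["tests"]["garden"]["p_value"],
                 report["tests"]["wild"]["r"], report["tests"]["wild"]["p_value"])

    manifest = RunManifest(
        config_hash=_config_hash(config),
        rng_seed=sc.rng_seed,
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs={str(p.relative_to(out)): _sha256(p) for p in written},
    )
    write_json(out / "manifest.json", manifest.to_dict())
    return manifest
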