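"""Species-wide outlier scan, logit-proportion meta-analysis, and reports.

The scan repeats the phylogenetic-prediction stage with *every* species in
turn held out, for every trait it has data for, flagging species whose
observed value falls outside the central 95% predictive interval.  The
meta-analysis then asks whether the focal species has exceptionally many
outlier traits: each species' outlier proportion is empirical-logit
transformed (+0.5 continuity correction, so species with zero outliers map
to a finite value), the number of traits tested enters as the predictor,
and the prediction stage is re-used to obtain a predictive distribution of
the focal species' proportion and a one-sided tail probability.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ou_shifts import ShiftSummary, shift_decision
from .phylo_predict import (
    MCMCConfig,
    OutlierResult,
    fit_rjmcmc,
    outlier_probability,
)
from .trait_data import MASS, TraitTable, trait_subset
from .treeio import TreeSet

__all__ = ["ScanResult", "MetaResult", "scan_all_species", "meta_predict_target", "report"]

logger = logging.getLogger(__name__)

SCAN_CONFIG = MCMCConfig(steps=20_100, burn_in=100, thin=100)


@dataclass
class ScanResult:
    """Outlier flags per species x trait, and per-species tallies."""

    flags: pd.DataFrame          # bool / NaN where species lacks data
    probabilities: pd.DataFrame  # two-sided tail probabilities, same shape
    alpha_level: float = 0.05
    skipped_traits: list[str] = field(default_factory=list)

    @property
    def tested(self) -> pd.Series:
        return self.flags.notna().sum(axis=1)

    @property
    def outliers(self) -> pd.Series:
        return (self.flags == True).sum(axis=1)  # noqa: E712  (NaN-safe)

    @property
    def proportions(self) -> pd.Series:
        t = self.tested
        return self.outliers.where(t > 0) / t.where(t > 0)


@dataclass
class MetaResult:
    logits: pd.Series
    tested: pd.Series
    draws: np.ndarray
    observed_logit: float
    observed_proportion: float
    tail_probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.tail_probability <= 1.0):
            raise ValueError("tail probability outside [0, 1]")


def scan_all_species(
    table: TraitTable,
    trees: TreeSet,
    config: MCMCConfig | None = None,
    alpha_level: float = 0.05,
    min_species: int = 3,
) -> ScanResult:
    """Hold out every (species, trait) cell in turn and flag outliers.

    A trait is skipped (with a log entry) when holding one species out would
    leave fewer than ``min_species`` species to fit on.
    """
    config = config or SCAN_CONFIG
    if config.seed is None:
        raise ValueError("config.seed is required")
    species = table.species
    traits = table.traits
    flags = pd.DataFrame(np.nan, index=species, columns=traits, dtype=object)
    probs = pd.DataFrame(np.nan, index=species, columns=traits)
    skipped = []
    for trait in traits:
        with_data, _, _ = trait_subset(table, trait)
        if len(with_data) - 1 < min_species:
            skipped.append(trait)
            logger.warning("trait %r skipped: only %d species", trait, len(with_data))
            continue
        for sp in with_data:
            # seed keyed on names so flags are invariant to row/column order
            ss = np.random.SeedSequence(
                [config.seed, zlib.crc32(trait.encode()), zlib.crc32(sp.encode())]
            )
            cfg = MCMCConfig(**{**config.__dict__,
                                "seed": int(ss.generate_state(1)[0] % 2**31)})
            chain = fit_rjmcmc(table, trees, trait, sp, cfg)
            p = outlier_probability(chain.draws, chain.observed)
            probs.loc[sp, trait] = p
            flags.loc[sp, trait] = bool(p < alpha_level)
    return ScanResult(flags=flags, probabilities=probs, alpha_level=alpha_level,
                      skipped_traits=skipped)


def empirical_logit(count: int, tested: int) -> float:
    """log((count + 0.5) / (tested - count + 0.5)); finite at 0 and at tested."""
    return float(np.log((count + 0.5) / (tested - count + 0.5)))


def meta_predict_target(
    scan: ScanResult,
    table: TraitTable,
    trees: TreeSet,
    target: str,
    config: MCMCConfig | None = None,
) -> MetaResult:
    """Predict the focal species' outlier proportion from the other species.

    One-sided tail probability: the (add-one-smoothed) fraction of
    predictive draws at or above the observed logit proportion -- small
    values mean the focal species has more outlier traits than predicted.
    """
    config = config or SCAN_CONFIG
    tested = scan.tested
    usable = tested[tested > 0]
    if target not in usable.index:
        raise KeyError(f"target {target!r} absent from scan results")
    if len(usable) < 10:
        raise ValueError("scan must cover at least 10 species")
    counts = scan.outliers
    logits = pd.Series(
        {sp: empirical_logit(int(counts[sp]), int(usable[sp])) for sp in usable.index}
    )
    meta_table = TraitTable(
        pd.DataFrame({MASS: usable.astype(float), "outlier_logit": logits}).sort_index(),
        target=target,
    )
    chain = fit_rjmcmc(meta_table, trees.prune(list(usable.index)), "outlier_logit",
                       target, config)
    obs = chain.observed
    nd = len(chain.draws)
    tail = float((np.sum(chain.draws >= obs) + 1) / (nd + 1))
    return MetaResult(
        logits=logits,
        tested=usable,
        draws=chain.draws,
        observed_logit=obs,
        observed_proportion=float(scan.proportions[target]),
        tail_probability=tail,
    )


def report(
    results: Sequence[OutlierResult],
    summaries: Sequence[ShiftSummary] | dict[str, ShiftSummary] | None,
    scan: ScanResult | None,
    meta: MetaResult | None,
    outdir: str,
) -> dict:
    """Write the prediction table, shift table, and combined verdicts.

    The combined per-trait verdict is 'both' / 'prediction' / 'shift' /
    'none' according to which stage(s) support exceptional evolution of the
    focal lineage for that trait.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pred_rows = []
    extreme = None
    if scan is not None:
        extreme = (scan.flags == True).sum(axis=0)  # noqa: E712
    for r in results:
        row = {
            "trait": r.trait,
            "n_species": r.n_species,
            "mean_prediction": r.mean,
            "sd_prediction": r.sd,
            "target_value": r.observed,
            "probability": r.probability,
            "flag": r.flag,
        }
        if extreme is not None and r.trait in extreme.index:
            row["extreme_species"] = int(extreme[r.trait])
        pred_rows.append(row)
    pred_df = pd.DataFrame(pred_rows)
    pred_df.to_csv(out / "prediction_table.csv", index=False)

    shift_map: dict[str, ShiftSummary] = {}
    if summaries:
        if isinstance(summaries, dict):
            shift_map = dict(summaries)
        else:
            raise TypeError("summaries must map trait -> ShiftSummary")
        sh_df = pd.DataFrame(
            [{
                "trait": t,
                "prop_models_with_shift": s.proportion,
                "rank": s.rank,
                "mean_shift": s.mean_shift,
                "sd_shift": s.sd_shift,
                "prop_positive": s.prop_positive,
            } for t, s in shift_map.items()]
        )
        sh_df.to_csv(out / "shift_table.csv", index=False)

    pred_traits = {r.trait for r in results}
    if shift_map and pred_traits != set(shift_map):
        diff = sorted(pred_traits ^ set(shift_map))
        raise ValueError(f"trait sets differ between stages: {diff}")

    verdicts = {}
    for r in results:
        pred_hit = bool(r.flag)
        shift_hit = False
        if r.trait in shift_map:
            shift_hit = shift_decision(shift_map[r.trait])["shifted"]
        verdicts[r.trait] = (
            "both" if pred_hit and shift_hit
            else "prediction" if pred_hit
            else "shift" if shift_hit
            else "none"
        )
    summary = {"verdicts": verdicts}
    if meta is not None:
        summary["meta"] = {
            "observed_proportion": meta.observed_proportion,
            "tail_probability": meta.tail_probability,
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
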