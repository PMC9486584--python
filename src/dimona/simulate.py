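"""Synthetic two-condition multi-omics data with planted differential blocks.

The generator emulates the structure of a stratified multi-omics cohort:
several layers (e.g. mRNA / protein / phosphosite) measured over the same
samples, with features organised into correlated blocks. Abundances follow a
latent-factor model: features of block ``b`` in sample ``j`` are

    x_ij = sqrt(rho_b) * z_bj + sqrt(1 - rho_b) * eps_ij,

so any two features of the block have correlation ``rho_b``. The block
latent ``z_bj`` is shared across layers, emulating the mRNA -> protein ->
phosphosite correspondence that same-name connectors exploit. A chosen set
of *perturbed* blocks uses ``rho - delta`` in condition B instead of
``rho`` — a differential co-regulation signal with known location. Entries
are set missing completely at random at a small rate to exercise
pairwise-complete correlation.

Drugs are planted on top: "differential" drugs target features inside
perturbed blocks and their simulated sensitivities shift between conditions
by a chosen effect size (in units of the replicate SD); "null" drugs target
unperturbed blocks and draw both conditions' sensitivities from the same
distribution. All randomness flows from the single ``seed`` through spawned
child generators, so each piece is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DrugTargetMap, OmicsMatrix, SensitivityTable

__all__ = ["FixtureSpec", "generate_grouped_omics", "generate_drug_data", "generate_all"]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic two-condition dataset.

    Defaults give three 300-feature layers, 40 samples per condition,
    10 blocks of which 3 are perturbed, and 50 drugs (40% targeting
    perturbed blocks) with 10 sensitivity replicates per condition.
    """

    layers: tuple[tuple[str, int], ...] = (
        ("mrna", 300),
        ("protein", 300),
        ("phosphosite", 300),
    )
    n_samples: int = 40
    n_blocks: int = 10
    within_block_corr: float = 0.8
    perturbed_blocks: tuple[int, ...] = (0, 1, 2)
    correlation_delta: float = 0.6
    n_drugs: int = 50
    targets_per_drug: int = 2
    frac_differential: float = 0.4
    target_layer: str = "protein"
    sensitivity_effect_size: float = 3.0
    n_replicates: int = 10
    missing_rate: float = 0.05
    noise_scale: float = 1.0
    conditions: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (
            self.within_block_corr,
            self.frac_differential,
            self.missing_rate,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0 <= self.within_block_corr - self.correlation_delta <= 1:
            raise ValueError(
                "perturbed-block correlation (rho - delta) must lie in [0, 1]"
            )
        if any(b >= self.n_blocks for b in self.perturbed_blocks):
            raise ValueError("perturbed block index out of range")
        if self.target_layer not in {name for name, _ in self.layers}:
            raise ValueError(f"target layer {self.target_layer!r} not among layers")

    def block_of(self, layer: str, n_features: int) -> np.ndarray:
        """Block index per feature: contiguous, near-equal blocks."""
        return np.arange(n_features) * self.n_blocks // n_features

    def feature_names(self, n_features: int) -> list[str]:
        # shared across layers so same-name connectors apply
        return [f"G{i:04d}" for i in range(n_features)]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_grouped_omics(spec: FixtureSpec) -> dict[str, dict[str, OmicsMatrix]]:
    """Generate block-correlated abundance matrices for both conditions.

    Returns ``{condition: {layer_name: OmicsMatrix}}``. Within-block
    correlation is ``within_block_corr`` everywhere except the perturbed
    blocks of condition B, where it is reduced by ``correlation_delta``.
    """
    rho0 = spec.within_block_corr
    rng_latent, rng_noise, rng_missing = _child_rngs(spec.seed, 3)
    out: dict[str, dict[str, OmicsMatrix]] = {}
    perturbed = set(spec.perturbed_blocks)
    for ci, condition in enumerate(spec.conditions):
        # one latent per (block, sample), shared across layers
        z = rng_latent.standard_normal((spec.n_blocks, spec.n_samples))
        sample_ids = [f"{condition}_s{j:03d}" for j in range(spec.n_samples)]
        out[condition] = {}
        for layer_name, n_feat in spec.layers:
            blocks = spec.block_of(layer_name, n_feat)
            rho = np.full(n_feat, rho0)
            if ci == 1:
                rho[np.isin(blocks, list(perturbed))] = rho0 - spec.correlation_delta
            eps = rng_noise.standard_normal((n_feat, spec.n_samples))
            x = (
                np.sqrt(rho)[:, None] * z[blocks]
                + np.sqrt(1 - rho)[:, None] * eps
            ) * spec.noise_scale
            if spec.missing_rate > 0:
                mask = rng_missing.random((n_feat, spec.n_samples)) < spec.missing_rate
                x = np.where(mask, np.nan, x)
            df = pd.DataFrame(
                x, index=spec.feature_names(n_feat), columns=sample_ids
            )
            out[condition][layer_name] = OmicsMatrix(
                layer_name=layer_name, condition=condition, data=df
            )
    return out


def generate_drug_data(spec: FixtureSpec) -> tuple[DrugTargetMap, SensitivityTable, dict[str, bool]]:
    """Plant drugs with known differential status.

    Returns ``(targets, sensitivities, is_differential)``. Differential
    drugs draw their targets from perturbed blocks of the target layer and
    their condition-B sensitivities are shifted by
    ``sensitivity_effect_size`` standard deviations; null drugs target
    unperturbed blocks with identically distributed sensitivities.
    """
    n_feat = dict(spec.layers)[spec.target_layer]
    blocks = spec.block_of(spec.target_layer, n_feat)
    names = np.array(spec.feature_names(n_feat))
    perturbed_feats = names[np.isin(blocks, list(spec.perturbed_blocks))]
    null_feats = names[~np.isin(blocks, list(spec.perturbed_blocks))]
    n_diff = round(spec.frac_differential * spec.n_drugs)
    if spec.targets_per_drug > min(len(perturbed_feats), len(null_feats)):
        raise ValueError("more targets per drug requested than available features")

    rng_targets, rng_sens = _child_rngs(spec.seed + 1, 2)
    entries: dict[str, set[tuple[str, str]]] = {}
    is_differential: dict[str, bool] = {}
    rows = []
    condA, condB = spec.conditions
    for i in range(spec.n_drugs):
        drug = f"drug{i:03d}"
        differential = i < n_diff
        pool = perturbed_feats if differential else null_feats
        chosen = rng_targets.choice(pool, size=spec.targets_per_drug, replace=False)
        entries[drug] = {(spec.target_layer, f) for f in chosen}
        is_differential[drug] = differential
        base = rng_sens.normal(0.0, 1.0)
        shift = spec.sensitivity_effect_size if differential else 0.0
        for r in range(spec.n_replicates):
            rows.append(
                {
                    "cell_line_id": f"cl{condA}{r:02d}",
                    "condition": condA,
                    "drug_id": drug,
                    "sensitivity": base + rng_sens.normal(0.0, 1.0),
                }
            )
            rows.append(
                {
                    "cell_line_id": f"cl{condB}{r:02d}",
                    "condition": condB,
                    "drug_id": drug,
                    "sensitivity": base + shift + rng_sens.normal(0.0, 1.0),
                }
            )
    sens = SensitivityTable(pd.DataFrame(rows))
    return DrugTargetMap(entries), sens, is_differential


def generate_all(spec: FixtureSpec):
    """Convenience: omics matrices plus drug data in one call."""
    omics = generate_grouped_omics(spec)
    targets, sens, is_differential = generate_drug_data(spec)
    return omics, targets, sens, is_differential
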