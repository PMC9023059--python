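"""Run-specification generation for the external prediction engine.

The prediction protocol deltas, relative to a default structure-prediction
pipeline: one recycle instead of three, no post-prediction relaxation,
stochastically subsampled MSAs of controlled depth, and — without templates —
all 5 networks at 10 predictions each (50 models per depth).  With templates
only the 2 template-capable networks are used, at 25 models each, with the
template similarity cutoff lowered from 10% to 1% and template subsampling
enabled.  This module only *emits* machine-readable manifests for a
ColabFold-compatible runner; it never invokes inference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

from altconf.errors import DomainError
from altconf.msa import default_cluster_count, global_identity

MANIFEST_SCHEMA_VERSION = 1

#: networks used without templates (engine model_1..model_5 convention)
ALL_NETWORKS = ["model_1", "model_2", "model_3", "model_4", "model_5"]
#: the two networks parametrized to use templates (engine default)
TEMPLATE_NETWORKS = ["model_1", "model_2"]


@dataclass
class RunSpec:
    """One complete, reproducible inference run: 50 models at one MSA depth."""

    msa_path: str
    extra_depth: int
    cluster_count: int
    seed: int
    recycles: int = 1
    relax: bool = False
    use_templates: bool = False
    template_ids: list[str] = field(default_factory=list)
    template_similarity_cutoff: float | None = None
    subsample_templates: bool = False
    networks: list[str] = field(default_factory=lambda: list(ALL_NETWORKS))
    models_per_network: int = 10
    schema_version: int = MANIFEST_SCHEMA_VERSION

    @property
    def total_models(self) -> int:
        return len(self.networks) * self.models_per_network

    def model_seeds(self) -> list[int]:
        """Per-model subsample seeds: base seed + model ordinal."""
        return [self.seed + i for i in range(self.total_models)]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunSpec":
        return cls(**json.loads(text))

    def command_lines(self, runner: str = "colabfold_runner") -> list[str]:
        """Shell commands for an external ColabFold-compatible executable,
        one per model, each with its own subsample seed."""
        lines = []
        for ordinal, seed in enumerate(self.model_seeds()):
            net = self.networks[ordinal // self.models_per_network]
            cmd = (
                f"{runner} --msa {self.msa_path} --network {net}"
                f" --max-extra-msa {self.extra_depth}"
                f" --max-msa-clusters {self.cluster_count}"
                f" --recycles {self.recycles} --seed {seed}"
                f" --out model_{ordinal:03d}.pdb"
            )
            if not self.relax:
                cmd += " --no-relax"
            if self.use_templates:
                cmd += (
                    f" --templates {','.join(self.template_ids)}"
                    f" --template-similarity-cutoff {self.template_similarity_cutoff}"
                )
                if self.subsample_templates:
                    cmd += " --subsample-templates"
            lines.append(cmd)
        return lines


def make_runspec(
    msa_path: str,
    extra_depth: int,
    templates: list[str] | None = None,
    seed: int = 0,
) -> RunSpec:
    """Build the protocol's run specification for one MSA depth.

    Without templates: 5 networks x 10 predictions.  With templates: the 2
    template-capable networks x 25 predictions, similarity cutoff 0.01,
    template subsampling on.  Either way 50 models, 1 recycle, no relaxation,
    and cluster count = ``default_cluster_count(extra_depth)``.
    """
    if extra_depth < 2:
        raise DomainError(f"extra_depth must be >= 2, got {extra_depth}")
    base = dict(
        msa_path=msa_path,
        extra_depth=extra_depth,
        cluster_count=default_cluster_count(extra_depth),
        seed=seed,
    )
    if templates:
        return RunSpec(
            **base,
            use_templates=True,
            template_ids=list(templates),
            template_similarity_cutoff=0.01,
            subsample_templates=True,
            networks=list(TEMPLATE_NETWORKS),
            models_per_network=25,
        )
    return RunSpec(**base, networks=list(ALL_NETWORKS), models_per_network=10)


def depth_ladder(min_depth: int = 16, max_depth: int = 5120) -> list[int]:
    """Default grid of MSA depths: powers of two from ``min_depth`` to 512,
    then 1024 and 5120, clipped to [min_depth, max_depth]."""
    if min_depth < 2:
        raise DomainError(f"min_depth must be >= 2, got {min_depth}")
    if min_depth > max_depth:
        raise DomainError(f"min_depth {min_depth} exceeds max_depth {max_depth}")
    ladder = [2**k for k in range(1, 10)] + [1024, 5120]  # 2..512, 1024, 5120
    grid = [d for d in ladder if min_depth <= d <= max_depth]
    if not grid:
        raise DomainError(
            f"no ladder depths fall in [{min_depth}, {max_depth}]; pass explicit depths"
        )
    return grid


def vet_templates(
    candidates: list[tuple[str, str]],
    query: str,
    conformation_labels: dict[str, str],
    wanted: str,
) -> list[tuple[str, float]]:
    """Keep candidate templates labelled with the wanted conformation.

    Labels come from human inspection upstream; identity to the query
    (Needleman-Wunsch percent identity) is *reported* alongside each kept id
    but never applied as an automatic cutoff.  Returns (id, identity%) pairs.
    """
    if not candidates:
        warnings.warn("empty template candidate list", stacklevel=2)
        return []
    kept = []
    for cid, seq in candidates:
        if conformation_labels.get(cid) == wanted:
            kept.append((cid, global_identity(query, seq)))
    if not kept:
        warnings.warn(f"no candidate labelled '{wanted}'", stacklevel=2)
    return kept
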