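"""Pipeline run configuration: every tunable threshold in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Thresholds and settings for an end-to-end barcode run.

    The defaults are the pipeline's canonical operating point: an F_ST
    threshold of 0.95 for calling a fixed or nearly fixed difference,
    a 50% within-group presence rule, 20-bp primer flanks, 5% fixedness
    leakage tolerance, 95%/90% coverage/identity for cross-pipeline
    duplicate removal, a 5-6 SNP per-group quota with an 80-SNP panel
    cap split into <=40-assay multiplexes, a >5% admixture rule for
    hybrid calls, and K = 1..6 with five replicates for cluster-number
    selection.  ``mcmc_burnin``/``mcmc_steps`` are provenance metadata
    describing the MCMC schedule the EM point estimate stands in for;
    they do not affect the fit.
    """

    fst_threshold: float = 0.95
    fst_estimator: str = "nei87"
    presence_threshold: float = 0.5
    flank_min: int = 20
    leakage_tol: float = 0.05
    coverage_min: float = 0.95
    identity_min: float = 0.90
    quota: tuple[int, int] = (5, 6)
    max_total: int = 80
    max_per_plex: int = 40
    admix_threshold: float = 0.05
    k_min: int = 1
    k_max: int = 6
    n_replicates: int = 5
    n_restarts: int = 3
    lambda_: float = 1.0
    mcmc_burnin: int = 100_000
    mcmc_steps: int = 1_000_000
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.quota = tuple(self.quota)
        checks = [
            (0.0 <= self.fst_threshold, "fst_threshold must be >= 0"),
            (0.0 <= self.presence_threshold <= 1.0, "presence_threshold in [0,1]"),
            (self.flank_min >= 0, "flank_min must be >= 0"),
            (0.0 <= self.leakage_tol <= 1.0, "leakage_tol in [0,1]"),
            (0.0 < self.coverage_min <= 1.0, "coverage_min in (0,1]"),
            (0.0 < self.identity_min <= 1.0, "identity_min in (0,1]"),
            (0 < self.quota[0] <= self.quota[1], "quota must satisfy 0 < min <= max"),
            (self.max_total >= 1 and self.max_per_plex >= 1, "caps must be >= 1"),
            (0.0 <= self.admix_threshold < 0.5, "admix_threshold in [0, 0.5)"),
            (1 <= self.k_min <= self.k_max, "K range must satisfy 1 <= k_min <= k_max"),
            (self.n_replicates >= 1 and self.n_restarts >= 1, "replicates/restarts >= 1"),
            (self.fst_estimator in ("nei87", "wc84"), "unknown fst estimator"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["quota"] = list(self.quota)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash identifying this configuration in provenance blocks."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
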