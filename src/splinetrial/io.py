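"""Plain-text serialization: scenario grids, OC tables, priors, manifests.

Everything the tool reads or writes is reviewable text: YAML for the design
configuration, CSV for tabular inputs/outputs, JSON for fitted priors.
Every tabular output is paired with a run manifest recording the config
snapshot, package version, master seed and a SHA-256 digest of each output
file, so a run can be replayed and verified exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .design import DesignConfig
from .simulate import OperatingCharacteristics, Scenario

__all__ = [
    "RunManifest",
    "read_scenarios_csv",
    "write_scenarios_csv",
    "oc_table",
    "write_oc_csv",
    "read_oc_csv",
]

SCENARIO_COLUMNS = ["label", "pi_t", "pi_c", "pi_disc", "n_per_arm",
                    "rule_family", "prior_family", "informativeness"]


@dataclass
class RunManifest:
    """Provenance record for one command invocation."""

    command: str
    master_seed: int | None
    config: dict
    outputs: dict = field(default_factory=dict)  # path -> sha256
    package_version: str = __version__
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def verify(self) -> bool:
        """Recompute output digests and compare with the recorded ones."""
        return all(sha256_file(p) == d for p, d in self.outputs.items())


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_scenarios_csv(path) -> list[Scenario]:
    # keep_default_na: a scenario labelled "null" is a label, not a NaN
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(SCENARIO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"scenario CSV is missing required column(s): {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(Scenario(
                pi_t=float(row.pi_t), pi_c=float(row.pi_c),
                pi_disc=float(row.pi_disc), n_per_arm=int(row.n_per_arm),
                rule_family=str(row.rule_family),
                prior_family=str(row.prior_family),
                informativeness=str(row.informativeness),
                label=str(row.label)))
        except ValueError as exc:
            raise ValueError(f"invalid scenario at CSV line {i + 2}: {exc}") \
                from exc
    return out


def write_scenarios_csv(scenarios, path) -> None:
    rows = [{
        "label": sc.label, "pi_t": sc.pi_t, "pi_c": sc.pi_c,
        "pi_disc": sc.pi_disc, "n_per_arm": sc.n_per_arm,
        "rule_family": sc.rule_family, "prior_family": sc.prior_family,
        "informativeness": sc.informativeness,
    } for sc in scenarios]
    pd.DataFrame(rows, columns=SCENARIO_COLUMNS).to_csv(path, index=False)


def oc_table(results: list[OperatingCharacteristics],
             cfg: DesignConfig) -> pd.DataFrame:
    """One row per scenario: the five indicators, their MC errors, and the
    operative thresholds as provenance columns."""
    rows = []
    for oc in results:
        sc = oc.scenario
        row = {
            "label": sc.label if sc else "",
            "pi_t": sc.pi_t if sc else float("nan"),
            "pi_c": sc.pi_c if sc else float("nan"),
            "pi_disc": sc.pi_disc if sc else float("nan"),
            "n_per_arm": sc.n_per_arm if sc else -1,
            "rule_family": sc.rule_family if sc else "",
            "prior_family": sc.prior_family if sc else "",
            "informativeness": sc.informativeness if sc else "",
        }
        row.update(oc.as_row())
        row.update({f"cfg_{k}": v for k, v in cfg.thresholds().items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_oc_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_oc_csv(path) -> pd.DataFrame:
    # only empty cells are missing; labels like "null" are literal
    return pd.read_csv(path, keep_default_na=False, na_values=[""])
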