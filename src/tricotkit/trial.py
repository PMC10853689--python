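"""Project metadata, package QR payloads and synthetic trial generation."""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSpec, TrialDesign, generate_design
from .io import design_to_csv_string
from .plackett import SimulationSpec, simulate_tricot_responses
from .pltree import CovariateTable
from .rankings import TricotResponse

__all__ = [
    "Project",
    "package_qr_payload",
    "parse_qr_payload",
    "synthesize_trial",
    "SyntheticTrial",
]

_SLUG_RE = re.compile(r"^[A-Za-z0-9_]+$")


@dataclass(frozen=True)
class Project:
    """A trial project: design plus registration metadata."""

    project_id: str
    title: str
    design: TrialDesign
    traits: tuple[str, ...] = ("overall",)
    collection_moments: tuple[str, ...] = ("post-harvest",)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.project_id or not _SLUG_RE.match(self.project_id):
            raise ValueError(
                f"project_id {self.project_id!r} must be a non-empty "
                "alphanumeric/underscore slug"
            )
        object.__setattr__(self, "traits", tuple(self.traits))
        object.__setattr__(
            self, "collection_moments", tuple(self.collection_moments)
        )
        if len(set(self.traits)) != len(self.traits):
            raise ValueError("traits must be unique")

    def to_json(self) -> str:
        doc = {
            "project_id": self.project_id,
            "title": self.title,
            "traits": list(self.traits),
            "collection_moments": list(self.collection_moments),
            "metadata": dict(self.metadata),
            "design": {
                "seed": self.design.spec.seed,
                "option_names": list(self.design.option_names),
                "packages": [
                    {"package_id": p.package_id, "options": list(p.options)}
                    for p in self.design.packages
                ],
            },
        }
        return json.dumps(doc, indent=2, ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Project":
        doc = json.loads(text)
        d = doc["design"]
        from .design import Package

        spec = DesignSpec(
            n_options=len(d["option_names"]),
            n_packages=len(d["packages"]),
            option_names=tuple(d["option_names"]),
            seed=d.get("seed", 0),
        )
        design = TrialDesign(
            spec=spec,
            packages=tuple(
                Package(package_id=p["package_id"], options=tuple(p["options"]))
                for p in d["packages"]
            ),
        )
        return cls(
            project_id=doc["project_id"],
            title=doc["title"],
            design=design,
            traits=tuple(doc.get("traits", ("overall",))),
            collection_moments=tuple(doc.get("collection_moments", ())),
            metadata=doc.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Project":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def package_qr_payload(project: Project, package_id: int) -> str:
    """Scannable label linking a physical package to its project record.

    Format: ``{project_id}-{package_id:04d}``. Rendering to an actual QR
    image is left to any external encoder.
    """
    if package_id < 1 or package_id > project.design.n_packages:
        raise ValueError(
            f"unknown package_id {package_id} (project has "
            f"{project.design.n_packages} packages)"
        )
    return f"{project.project_id}-{package_id:04d}"


def parse_qr_payload(payload: str) -> tuple[str, int]:
    """Inverse of package_qr_payload."""
    project_id, _, tail = payload.rpartition("-")
    if not project_id or not tail.isdigit():
        raise ValueError(f"malformed QR payload {payload!r}")
    return project_id, int(tail)


@dataclass(frozen=True)
class SyntheticTrial:
    project: Project
    responses: list[TricotResponse]
    covariates: CovariateTable
    true_log_worths: dict[str, np.ndarray]  # per environment level
    observations_csv: str
    design_csv: str


def synthesize_trial(
    t: int,
    n: int,
    log_worths: np.ndarray,
    covariate_effect: float = 0.0,
    seed: int = 0,
    response_rate: float = 0.9,
    trait: str = "overall",
    effect_mode: str = "reverse",
    project_id: str = "synth",
) -> SyntheticTrial:
    """Generate a complete synthetic trial with a binary environment covariate.

    Packages are split evenly between environments "low" and "high"
    (seeded). Environment "low" uses the base log-worths; "high" uses them
    reversed (``effect_mode='reverse'``) or shifted (``'shift'``), scaled by
    ``covariate_effect``. Effect 0 makes both environments identical. The
    output is self-contained: the full fit/tree/report pipeline runs on it
    with no external data.
    """
    log_worths = np.asarray(log_worths, dtype=float)
    if len(log_worths) != t:
        raise ValueError("log_worths length must equal t")
    rng = np.random.default_rng(seed)
    option_names = tuple(f"option_{i + 1:02d}" for i in range(t))
    design = generate_design(
        DesignSpec(
            n_options=t,
            n_packages=n,
            option_names=option_names,
            seed=int(rng.integers(2**31)),
        )
    )
    env = np.array(["low"] * (n - n // 2) + ["high"] * (n // 2))
    rng.shuffle(env)

    base = log_worths - log_worths.mean()
    if effect_mode == "reverse":
        alt = (1 - covariate_effect) * base + covariate_effect * base[::-1]
    elif effect_mode == "shift":
        shift = np.linspace(-0.5, 0.5, t) * covariate_effect
        alt = base + shift
    else:
        raise ValueError(f"unknown effect_mode {effect_mode!r}")
    alt = alt - alt.mean()
    worths_by_env = {"low": base, "high": alt}

    responses: list[TricotResponse] = []
    for level in ("low", "high"):
        ids = [i + 1 for i in range(n) if env[i] == level]
        if not ids:
            continue
        sub_design = TrialDesign(
            spec=DesignSpec(
                n_options=t,
                n_packages=len(ids),
                option_names=option_names,
                seed=0,
            ),
            packages=tuple(
                type(design.packages[0])(
                    package_id=k + 1, options=design.packages[pid - 1].options
                )
                for k, pid in enumerate(ids)
            ),
        )
        sim = simulate_tricot_responses(
            SimulationSpec(
                design=sub_design,
                log_worths=worths_by_env[level],
                seed=int(rng.integers(2**31)),
                response_rate=response_rate,
                trait=trait,
            )
        )
        for local, pid in zip(sim, ids):
            responses.append(
                TricotResponse(
                    package_id=pid,
                    trait=local.trait,
                    best=local.best,
                    worst=local.worst,
                )
            )
    responses.sort(key=lambda r: r.package_id)

    cov = CovariateTable(
        pd.DataFrame(
            {
                "package_id": np.arange(1, n + 1),
                "environment": env,
                "env_high": (env == "high").astype(int),
            }
        )
    )
    project = Project(
        project_id=project_id,
        title=f"Synthetic trial ({t} options, {n} packages)",
        design=design,
        traits=(trait,),
    )

    import csv as _csv
    import io as _sio

    buf = _sio.StringIO()
    writer = _csv.writer(buf)
    writer.writerow(["package_id", "trait", "best", "worst"])
    for r in responses:
        writer.writerow([r.package_id, r.trait, r.best or "", r.worst or ""])

    return SyntheticTrial(
        project=project,
        responses=responses,
        covariates=cov,
        true_log_worths=worths_by_env,
        observations_csv=buf.getvalue(),
        design_csv=design_to_csv_string(design),
    )
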