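"""File readers/writers and run configuration shared by the CLI tools.

Interchange formats are deliberately plain: delimited text with headers
for pedigree and phenotypes, labelled CSV for covariance matrices, and
YAML for model/run configuration.  Every run is reproducible from
(config, seed); outputs carry both in a header comment.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree
from .sad import CrossSADSpec, PolyFn, SADSpec, TimeGrid
from .mixed_model import ModelSpec

__all__ = [
    "read_phenotypes",
    "read_pedigree",
    "write_covariance_csv",
    "read_covariance_csv",
    "model_spec_to_dict",
    "model_spec_from_dict",
    "load_model_config",
    "save_model_config",
    "configure_logging",
    "RunConfig",
]

log = logging.getLogger("sadige")

REQUIRED_PHENOTYPE_COLUMNS = ("animal", "group", "week", "adg")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table (CSV with header).

    Requires columns animal, group, week, adg (litter optional);
    rejects duplicate animal x week records and non-numeric ADG.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(REQUIRED_PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    df["week"] = pd.to_numeric(df["week"], errors="raise").astype(int)
    try:
        df["adg"] = pd.to_numeric(df["adg"], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric adg value ({exc})") from exc
    dup = df.duplicated(subset=["animal", "week"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"{path}: duplicate record for animal {row['animal']!r} "
            f"week {row['week']}"
        )
    return df


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3-column pedigree file (animal, sire, dam; 0/NA unknown)."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: pedigree needs 3 columns (animal, sire, dam)")
    if len(df) == 0:
        log.warning("%s: empty pedigree file", path)
        return Pedigree((), np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))
    return Pedigree.from_frame(df)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.to_frame().to_csv(path, index=False)


def write_covariance_csv(
    matrix: np.ndarray, labels: list[str], path: str | Path, meta: str = ""
) -> None:
    """Labelled covariance matrix as CSV (12 significant digits)."""
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        fh.write("," + ",".join(labels) + "\n")
        for lab, row in zip(labels, matrix):
            fh.write(lab + "," + ",".join(f"{v:.12g}" for v in row) + "\n")


def read_covariance_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0, comment="#")
    return df.to_numpy(dtype=float), list(df.columns)


# ---------------------------------------------------------------------------
# model configuration


def _poly_to_list(fn: PolyFn) -> list[float]:
    return [float(c) for c in fn.coefficients]


def _spec_to_dict(spec: SADSpec) -> dict:
    return {
        "order": spec.order,
        "antedependence": [_poly_to_list(f) for f in spec.antedependence_fns],
        "innovation_logvar": _poly_to_list(spec.innovation_logvar_fn),
    }


def _spec_from_dict(d: dict) -> SADSpec:
    fns = tuple(PolyFn(tuple(c)) for c in d.get("antedependence", []))
    if len(fns) != d.get("order", len(fns)):
        raise ValueError("antedependence function count does not match order")
    return SADSpec(fns, PolyFn(tuple(d["innovation_logvar"])))


def model_spec_to_dict(model: ModelSpec) -> dict:
    out: dict = {
        "grid": {
            "weeks": list(model.grid.weeks),
            "shift": model.grid.shift,
            "scale": model.grid.scale,
        },
        "permanent": _spec_to_dict(model.permanent),
    }
    if isinstance(model.genetic, CrossSADSpec):
        out["genetic"] = {
            "direct": _spec_to_dict(model.genetic.primary_spec),
            "indirect": _spec_to_dict(model.genetic.secondary_spec),
            "cross": _poly_to_list(model.genetic.cross_fn),
        }
    elif isinstance(model.genetic, SADSpec):
        out["genetic"] = {"direct": _spec_to_dict(model.genetic)}
    if model.group is not None:
        out["group"] = _spec_to_dict(model.group)
    if model.litter is not None:
        out["litter"] = _spec_to_dict(model.litter)
    if model.fixed_factors:
        out["fixed_factors"] = list(model.fixed_factors)
    return out


_KNOWN_KEYS = {"grid", "genetic", "group", "litter", "permanent", "fixed_factors"}


def model_spec_from_dict(d: dict) -> ModelSpec:
    unknown = set(d) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown model config keys: {sorted(unknown)}")
    g = d["grid"]
    grid = TimeGrid(
        tuple(g["weeks"]), float(g.get("shift", 0.0)), float(g.get("scale", 1.0))
    )
    genetic = None
    if "genetic" in d:
        gd = d["genetic"]
        direct = _spec_from_dict(gd["direct"])
        if "indirect" in gd:
            genetic = CrossSADSpec(
                direct,
                _spec_from_dict(gd["indirect"]),
                PolyFn(tuple(gd.get("cross", [0.0]))),
            )
        else:
            genetic = direct
    return ModelSpec(
        grid=grid,
        genetic=genetic,
        group=_spec_from_dict(d["group"]) if "group" in d else None,
        permanent=_spec_from_dict(d["permanent"]),
        litter=_spec_from_dict(d["litter"]) if "litter" in d else None,
        fixed_factors=tuple(d.get("fixed_factors", ())),
    )


def save_model_config(model: ModelSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_spec_to_dict(model), fh, sort_keys=False)


def load_model_config(path: str | Path) -> ModelSpec:
    with open(path) as fh:
        return model_spec_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# run configuration / logging


@dataclass
class RunConfig:
    """Validated CLI run configuration."""

    seed: int = 0
    out_dir: Path = Path(".")
    n_samples: int = 10_000
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seed = int(self.seed)
        self.out_dir = Path(self.out_dir)
        for key, p in self.paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")

    @property
    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def config_hash(self) -> str:
        body = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(body).hexdigest()[:12]


def configure_logging(out_dir: str | Path | None = None, seed: int | None = None,
                      config_hash: str = "") -> logging.Logger:
    """Console + optional file logging; records seed and config hash."""
    logger = logging.getLogger("sadige")
    logger.setLevel(logging.INFO)
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(h)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(Path(out_dir) / "run.log")
        fh.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(fh)
    if seed is not None:
        logger.info("seed=%d config_hash=%s", seed, config_hash)
    return logger
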