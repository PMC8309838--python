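"""The SVM hyperparameter search space and genome decoding.

The space is a grid over six nu-SVM parameters.  Not every parameter is
meaningful for every kernel (an RBF machine ignores ``coef0`` and
``degree``), so a configuration's *canonical form* keeps only the
kernel-relevant parameters; two configurations that differ solely in
irrelevant parameters are the same model.  Counting distinct canonical
configurations over the default lists gives the exhaustive-search size of
540,560 models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

PARAM_ORDER = ("tolerance", "gamma", "coef0", "nu", "degree", "kernel")

_DECADES = [10.0**e for e in range(-8, 0)]  # 1e-8 .. 0.1
_TENTHS = [round(0.2 + 0.1 * i, 1) for i in range(50)]  # 0.2 .. 5.1
GAMMA_VALUES: Tuple[float, ...] = tuple(_DECADES + _TENTHS)  # 58 values
TOLERANCE_VALUES: Tuple[float, ...] = tuple(10.0**e for e in range(-1, -9, -1))
NU_VALUES: Tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6)
DEGREE_VALUES: Tuple[int, ...] = (1, 2, 3)
KERNEL_VALUES: Tuple[str, ...] = ("rbf", "poly", "sigmoid")

DEFAULT_RELEVANCE: Dict[str, Tuple[str, ...]] = {
    "rbf": ("tolerance", "gamma", "nu"),
    "poly": ("tolerance", "gamma", "coef0", "nu", "degree"),
    "sigmoid": ("tolerance", "gamma", "coef0", "nu"),
}


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered lists of admissible values per SVM parameter.

    ``relevance`` maps each kernel to the parameters it actually uses;
    tolerance, gamma and nu are relevant to every kernel.
    """

    tolerance: Tuple[float, ...] = TOLERANCE_VALUES
    gamma: Tuple[float, ...] = GAMMA_VALUES
    coef0: Tuple[float, ...] = GAMMA_VALUES
    nu: Tuple[float, ...] = NU_VALUES
    degree: Tuple[int, ...] = DEGREE_VALUES
    kernel: Tuple[str, ...] = KERNEL_VALUES
    relevance: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_RELEVANCE)
    )

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            if len(self.values_of(name)) == 0:
                raise ValueError(f"parameter list {name!r} is empty")
        for kernel in self.kernel:
            rel = self.relevance.get(kernel)
            if rel is None:
                raise ValueError(f"no relevance set for kernel {kernel!r}")
            for required in ("tolerance", "gamma", "nu"):
                if required not in rel:
                    raise ValueError(
                        f"relevance of kernel {kernel!r} must contain {required!r}"
                    )

    def values_of(self, name: str) -> Sequence:
        if name not in PARAM_ORDER:
            raise ValueError(f"unknown parameter {name!r}")
        return getattr(self, name)

    def list_lengths(self) -> Tuple[int, ...]:
        return tuple(len(self.values_of(p)) for p in PARAM_ORDER)


def build_parameter_space() -> ParameterSpace:
    """The default search space (8 x 58 x 58 x 5 x 3 values, 3 kernels)."""
    return ParameterSpace()


@dataclass(frozen=True)
class ModelConfig:
    """One concrete SVM configuration (a decoded genome)."""

    tolerance: float
    gamma: float
    coef0: float
    nu: float
    degree: int
    kernel: str

    def canonical(self, space: ParameterSpace) -> tuple:
        """Kernel plus kernel-relevant parameter values, in fixed order.

        Configurations with the same canonical form train the same model.
        """
        rel = space.relevance[self.kernel]
        return (self.kernel,) + tuple(
            getattr(self, p) for p in PARAM_ORDER if p != "kernel" and p in rel
        )

    def to_dict(self) -> dict:
        return {p: getattr(self, p) for p in PARAM_ORDER}


def count_exhaustive(space: ParameterSpace) -> int:
    """Number of distinct canonical configurations in the space.

    Sum over kernels of the product of that kernel's relevant-parameter
    list lengths.
    """
    total = 0
    for kernel in space.kernel:
        prod = 1
        for p in space.relevance[kernel]:
            prod *= len(space.values_of(p))
        total += prod
    return total


# A model genome is a tuple of 6 indices into the parameter lists, in
# PARAM_ORDER: (tolerance, gamma, coef0, nu, degree, kernel).
ModelGenome = Tuple[int, int, int, int, int, int]


def validate_genome(genome: Sequence[int], space: ParameterSpace) -> None:
    if len(genome) != len(PARAM_ORDER):
        raise ValueError(f"genome must have {len(PARAM_ORDER)} genes")
    for idx, name in zip(genome, PARAM_ORDER):
        n = len(space.values_of(name))
        if not 0 <= int(idx) < n:
            raise ValueError(
                f"gene {name!r} index {idx} out of range [0, {n})"
            )


def decode(genome: Sequence[int], space: ParameterSpace) -> ModelConfig:
    """Index-to-value lookup of a genome into a trainable configuration."""
    validate_genome(genome, space)
    kwargs = {
        name: space.values_of(name)[int(idx)]
        for idx, name in zip(genome, PARAM_ORDER)
    }
    return ModelConfig(**kwargs)


def encode(config: ModelConfig, space: ParameterSpace) -> ModelGenome:
    """Inverse of :func:`decode` (each value must be a list member)."""
    genome = []
    for name in PARAM_ORDER:
        values = list(space.values_of(name))
        try:
            genome.append(values.index(getattr(config, name)))
        except ValueError:
            raise ValueError(
                f"config value {getattr(config, name)!r} not in the "
                f"{name!r} list"
            ) from None
    return tuple(genome)
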