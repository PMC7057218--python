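import numpy as np
import pytest

from cvfold import fixtures as fx
from cvfold.annotation import annotate_structure
from cvfold.fold_library import build_fold_matrix


@pytest.fixture(scope="session")
def helix12():
    return fx.build_ideal_element("ah", 12)


@pytest.fixture(scope="session")
def strand10():
    return fx.build_ideal_element("bs", 10)


@pytest.fixture(scope="session")
def coil12():
    return fx.build_ideal_element("coil", 12)


def mixed_fold_spec(noise_sigma: float = 0.0, seed: int = 0) -> fx.FixtureSpec:
    """Two antiparallel strands packed at sheet distance plus one helix."""
    R = fx.rotation_matrix([1, 0, 0], 180.0)
    return fx.FixtureSpec(elements=[
        fx.ElementSpec("bs", 7),
        fx.ElementSpec("bs", 7, rotation=R, translation=np.array([0, 0, 4.8])),
        fx.ElementSpec("ah", 10, translation=np.array([0, 0, 10.0])),
    ], noise_sigma=noise_sigma, seed=seed)


@pytest.fixture(scope="session")
def mixed_fold():
    stretches, truth = fx.assemble_fold(mixed_fold_spec())
    return stretches, truth


@pytest.fixture(scope="session")
def mixed_fold_annotated(mixed_fold):
    stretches, _ = mixed_fold
    return annotate_structure(stretches)


@pytest.fixture(scope="session")
def mixed_fold_matrix(mixed_fold_annotated):
    return build_fold_matrix(mixed_fold_annotated)


def random_target_spec(rng: np.random.Generator, max_elements: int = 4
                       ) -> fx.FixtureSpec:
    """A random multi-element fixture used as a fold-search target."""
    n_el = int(rng.integers(2, max_elements + 1))
    elements = []
    for _ in range(n_el):
        kind = ("ah", "bs")[int(rng.integers(0, 2))]
        elements.append(fx.ElementSpec(
            kind, int(rng.integers(7, 12)),
            rotation=fx.random_rotation(rng),
            translation=rng.normal(scale=15, size=3)))
    return fx.FixtureSpec(elements=elements, noise_sigma=0.1,
                          seed=int(rng.integers(2 ** 31)))


def embedded_fold_target_spec(rng: np.random.Generator,
                              base: fx.FixtureSpec | None = None,
                              max_decoys: int = 3) -> fx.FixtureSpec:
    """A target that contains the mixed fold (rigidly moved as a whole,
    mildly perturbed) plus far-away decoy elements."""
    base = base or mixed_fold_spec()
    R = fx.random_rotation(rng)
    t = rng.normal(scale=20, size=3)
    elements = [fx.ElementSpec(el.kind, el.length, R @ el.rotation,
                               R @ el.translation + t)
                for el in base.elements]
    for k in range(int(rng.integers(0, max_decoys + 1))):
        kind = ("ah", "bs")[int(rng.integers(0, 2))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        elements.append(fx.ElementSpec(
            kind, int(rng.integers(7, 12)),
            rotation=fx.random_rotation(rng),
            translation=t + direction * rng.uniform(70, 110)))
    return fx.FixtureSpec(elements=elements, noise_sigma=0.1,
                          seed=int(rng.integers(2 ** 31)))
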