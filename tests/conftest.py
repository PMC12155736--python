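import numpy as np
import pytest

from rdpet.geometry import ImageGrid, SinogramGeometry, build_system_model
from rdpet.objective import ObjectiveBundle, RDPParams
from rdpet.phantom import (
    Ellipse,
    PhantomSpec,
    default_desk_setup,
    simulate_dataset,
)
from rdpet.sampling import partition_views


@pytest.fixture(scope="session")
def tiny_grid():
    return ImageGrid((16, 16), (2.5, 2.5))


@pytest.fixture(scope="session")
def tiny_geom():
    return SinogramGeometry(n_views=12, n_radial=24, radial_spacing=2.5)


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(
        ellipses=(
            Ellipse((0.0, 0.0), (14.0, 17.0), 0.0, activity=1.0, is_background=True),
            Ellipse((-4.0, -5.0), (5.0, 5.0), 0.0, activity=3.0),
        ),
        body_ellipse=0,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_grid, tiny_geom, tiny_spec):
    from rdpet.phantom import make_phantom

    _, mu, _ = make_phantom(tiny_spec, tiny_grid)
    return build_system_model(
        tiny_grid, tiny_geom, mu_image=mu, resolution_fwhm=4.0,
        detection_efficiency=2e-3,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_model, tiny_spec):
    return simulate_dataset(tiny_model, tiny_spec, true_counts=2e4,
                            background_fraction=0.25, seed=7)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_dataset):
    """4-subset objective bundle on the tiny dataset, moderate RDP weight."""
    ds = tiny_dataset
    scheme = partition_views(ds.model.geom.n_views, 4)
    rdp = RDPParams(beta=1e-3, gamma=2.0, epsilon=0.05,
                    spacing=ds.model.grid.spacing)
    return ObjectiveBundle(ds.model, ds.y, ds.r, scheme, rdp)


@pytest.fixture(scope="session")
def desk():
    """Default desk-scale scanner + phantom (the study conditions)."""
    grid, geom, spec, model = default_desk_setup()
    return {"grid": grid, "geom": geom, "spec": spec, "model": model}


@pytest.fixture(scope="session")
def desk_dataset(desk):
    return simulate_dataset(desk["model"], desk["spec"], true_counts=5e5,
                            background_fraction=0.25, seed=0)
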