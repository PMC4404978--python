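"""Generate the synthetic study world and biased occurrence samples.

Writes the environmental stack, classification rasters, virtual-species
truth surfaces, native-range table, and the raw G/H occurrence table under
``results/world/``.  Species span germplasm shares from 0 (never collected)
to 0.8 (genebank-dominated) so the downstream gap analysis exercises the
whole priority scale.
"""

import json

import numpy as np

from common import (
    N_RECORDS,
    N_SPECIES,
    SEED,
    STACK_DIR,
    TRUTH_DIR,
    WORLD_DIR,
    study_config,
)
from cwrgap.geodata import write_occurrences, write_raster
from cwrgap.synthetic import (
    generate_environment,
    make_virtual_species,
    sample_occurrences,
)


def main() -> None:
    cfg = study_config()
    env = generate_environment(cfg)
    rng = np.random.default_rng((SEED, 0x57DD))

    for d in (WORLD_DIR, STACK_DIR, TRUTH_DIR):
        d.mkdir(parents=True, exist_ok=True)

    for name in env.stack.names:
        write_raster(env.stack.layers[name], STACK_DIR / f"{name}.asc")
    write_raster(env.ecosystems, WORLD_DIR / "ecosystems.asc")
    write_raster(env.countries, WORLD_DIR / "countries.asc")
    write_raster(env.coast_distance, WORLD_DIR / "coast_distance.asc")
    write_raster(env.harvested_area, WORLD_DIR / "harvested_area.asc")

    species = [
        make_virtual_species(env, cfg, rng, f"species_{i + 1:02d}")
        for i in range(N_SPECIES)
    ]
    g_fractions = np.linspace(0.0, 0.8, N_SPECIES)

    all_sets, native_rows, manifest_species = [], [], {}
    for sp, gf in zip(species, g_fractions):
        res = sample_occurrences(sp, env, cfg, n_records=N_RECORDS,
                                 g_fraction=float(gf))
        all_sets.append(res.occurrences)
        write_raster(res.truth, TRUTH_DIR / f"{sp.name}.asc")
        native_rows.append(
            f"{sp.name},{';'.join(f'C{c:02d}' for c in sorted(sp.native_countries))},"
            f"{'' if sp.coastal_limit_km is None else sp.coastal_limit_km}"
        )
        manifest_species[sp.name] = {
            "niche_center": {k: float(v) for k, v in sp.niche_center.items()},
            "niche_width": {k: float(v) for k, v in sp.niche_width.items()},
            "g_fraction": float(gf),
            "injected_errors": res.injected,
        }
        print(
            f"{sp.name}: {len(res.occurrences)} records "
            f"(G share {gf:.2f}), injected {res.injected}"
        )

    write_occurrences(all_sets, WORLD_DIR / "occurrences.csv")
    (WORLD_DIR / "native_ranges.csv").write_text(
        "taxon,countries,coastal_limit_km\n" + "\n".join(native_rows) + "\n"
    )
    (WORLD_DIR / "manifest.json").write_text(json.dumps(
        {
            "seed": SEED,
            "variables": env.stack.names,
            "roles": env.stack.roles,
            "n_land_cells": int(env.land.sum()),
            "species": manifest_species,
        },
        indent=2,
    ))
    print(f"world written to {WORLD_DIR} "
          f"({int(env.land.sum())} land cells, {len(env.stack.names)} layers)")


if __name__ == "__main__":
    main()
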