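"""Station observations -> regional daily weather via IDW + zonal means.

Interpolates a small synthetic station network to a lon/lat grid with
inverse-distance weighting (power 2, great-circle distances) and averages
the cells inside each region box. The regional series must stay inside the
daily range of the station values — interpolation cannot extrapolate.
"""

from tempmort import exposure, synth

cfg = synth.WorldConfig(seed=2, n_regions=4, n_stations=8, n_days=365)
stations = synth.generate_stations(cfg)

cell = 0.5
ext = synth.EXTENT
grid = exposure.Grid(ext["lon_min"], ext["lat_min"], cell,
                     int((ext["lon_max"] - ext["lon_min"]) / cell),
                     int((ext["lat_max"] - ext["lat_min"]) / cell))
masks = synth.region_box_masks(cfg, grid)
regional = exposure.build_region_series(stations, grid, masks)

print(f"{len(regional)} region-days from {cfg.n_stations} stations")
day = regional["date"].iloc[0]
st_day = stations[stations["date"] == day]
print(f"\nfirst day ({day.date()}): station tmean spans "
      f"[{st_day['tmean'].min():.2f}, {st_day['tmean'].max():.2f}] degC")
for _, row in regional[regional["date"] == day].iterrows():
    print(f"  {row['region_id']}: tmean {row['tmean']:.2f} degC, "
          f"rh {row['rh']:.1f}%")
# every regional value lies inside the day's station range: IDW output is a
# convex combination of station values
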