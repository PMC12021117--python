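"""Parse a PVGIS v5.2 seriescalc payload into a normalized hourly series.

The reader accepts the raw CSV (or JSON) response of the PVGIS web API,
extracts the global-irradiance column, checks the hourly grid is uniform,
and normalizes by the maximum over the whole record.  The payload below is a
tiny synthetic stand-in with the same dialect as a real response; a real
record is fetched once with `adaptrack fetch-pvgis --out <file>` (network
required) and then read the same way.
"""

from adaptrack import read_pvgis_hourly

SYNTHETIC_PVGIS_CSV = """Latitude (decimal degrees):\t45.000
Longitude (decimal degrees):\t0.000
Radiation database:\tPVGIS-ERA5

time,G(i),H_sun,T2m,WS10m,Int
20150621:0410,0.0,0.0,12.1,2.0,0.0
20150621:0510,95.0,6.2,12.4,2.1,0.0
20150621:0610,260.0,15.0,13.0,2.0,0.0
20150621:0710,430.0,24.1,14.1,1.9,0.0
20150621:0810,610.0,33.2,15.0,1.8,0.0
20150621:0910,760.0,41.8,16.2,1.8,0.0
20150621:1010,860.0,49.3,17.0,1.7,0.0

G(i): Global irradiance on the inclined plane (W/m2)
"""

series = read_pvgis_hourly(SYNTHETIC_PVGIS_CSV)
print(f"parsed {len(series)} hourly samples "
      f"({series.index[0]} .. {series.index[-1]} UTC)")
for stamp, value in zip(series.index, series.values):
    print(f"  {stamp}  {value:.4f}")
print()
print("Values are dimensionless fractions of the record maximum (here the")
print("last sample); on a full multi-year record the divisor is the global")
print("maximum over the entire dataset, so seasons remain comparable.")
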