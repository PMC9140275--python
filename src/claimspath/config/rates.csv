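year,fx_jpy_per_usd,cpi
2008,107.7,96.8
2009,90.4,95.5
2010,91.3,94.8
2011,82.6,94.5
2012,76.9,94.5
2013,89.2,94.9
2014,103.9,97.5
2015,118.3,98.2
2016,118.2,98.1
2017,114.7,98.6
2018,110.7,99.5
2019,108.0,100.0
2020,109.4,100.0
2021,103.8,99.8
2022,115.1,102.3
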