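Model,Scenario,Region,Variable,Unit,2000,2001,2002,2003,2004,2005,2006,2007,2008,2009,2010,2011,2012,2013,2014,2015,2016,2017,2018,2019,2020,2021,2022,2023,2024,2025,2026,2027,2028,2029,2030,2031,2032,2033,2034,2035,2036,2037,2038,2039,2040,2041,2042,2043,2044,2045,2046,2047,2048,2049,2050,2051,2052,2053,2054,2055,2056,2057,2058,2059,2060,2061,2062,2063,2064,2065,2066,2067,2068,2069,2070,2071,2072,2073,2074,2075,2076,2077,2078,2079,2080,2081,2082,2083,2084,2085,2086,2087,2088,2089,2090,2091,2092,2093,2094,2095,2096,2097,2098,2099,2100
herdclim,BAU,World,Emissions|CH4|Livestock,Mt CH4/yr,105.7354243,106.4312337,107.1316219,107.8366192,108.5462558,109.2605624,109.9795695,110.7033081,111.4318095,112.1651049,112.9032258,113.6462041,114.3940716,115.1468607,115.9046035,116.6673329,117.4350815,118.2078823,118.9857688,119.7687742,120.5569324,121.3502771,122.1488426,122.9526632,123.7617734,124.5762081,125.3960024,126.2211914,127.0518108,127.8878961,128.7294835,129.576609,130.4293093,131.2876208,132.1515806,133.0212258,133.8965939,134.7777225,135.6646495,136.5574131,137.4560516,138.3606038,139.2711085,140.187605,141.1101326,142.0387311,142.9734403,143.9143006,144.8613523,145.8146363,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935,146.7741935
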