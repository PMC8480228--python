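Model,Scenario,Region,Variable,Unit,2000,2001,2002,2003,2004,2005,2006,2007,2008,2009,2010,2011,2012,2013,2014,2015,2016,2017,2018,2019,2020,2021,2022,2023,2024,2025,2026,2027,2028,2029,2030,2031,2032,2033,2034,2035,2036,2037,2038,2039,2040,2041,2042,2043,2044,2045,2046,2047,2048,2049,2050,2051,2052,2053,2054,2055,2056,2057,2058,2059,2060,2061,2062,2063,2064,2065,2066,2067,2068,2069,2070,2071,2072,2073,2074,2075,2076,2077,2078,2079,2080,2081,2082,2083,2084,2085,2086,2087,2088,2089,2090,2091,2092,2093,2094,2095,2096,2097,2098,2099,2100
herdclim,1.5C-consistent,World,Emissions|CO2,Gt CO2/yr,28.68405646,28.97089703,29.260606,29.55321206,29.84874418,30.14723162,30.44870394,30.75319097,31.06072288,31.37133011,31.68504341,32.00189385,32.32191279,32.64513191,32.97158323,33.30129907,33.63431206,33.97065518,34.31036173,34.65346535,35,33.285,31.654035,30.10298728,28.62794091,27.2251718,25.89113839,24.6224726,23.41597145,22.26858885,21.17742799,20.0686195,18.97831963,17.90757527,16.85743335,15.82894076,14.82314442,13.84109123,12.88382809,11.95240192,11.04785963,10.17124812,9.323614289,8.492262255,7.666280827,6.849393973,6.04532566,5.257799858,4.490540534,3.747271657,3.031717196,2.347601117,1.69864739,1.088579982,0.5211228631,0,-0.4965401429,-0.9918493626,-1.484604082,-1.973480725,-2.457155715,-2.934305474,-3.403606426,-3.863734994,-4.313367601,-4.751180671,-5.175850627,-5.586053891,-5.980466888,-6.35776604,-6.71662777,-7.055728502,-7.37374466,-7.669352665,-7.941228942,-8.188049913,-8.408492002,-8.601231632,-8.764945226,-8.898309208,-9,-9.084335237,-9.166369069,-9.245882689,-9.322657293,-9.396474077,-9.467114236,-9.534358963,-9.597989455,-9.657786907,-9.713532513,-9.765007469,-9.81199297,-9.854270211,-9.891620387,-9.923824692,-9.950664323,-9.971920475,-9.987374341,-9.996807118,-10
herdclim,1.5C-consistent,World,Emissions|CH4|Livestock,Mt CH4/yr,105.7354243,106.4312337,107.1316219,107.8366192,108.5462558,109.2605624,109.9795695,110.7033081,111.4318095,112.1651049,112.9032258,113.6462041,114.3940716,115.1468607,115.9046035,116.6673329,117.4350815,118.2078823,118.9857688,119.7687742,120.5569324,118.3494163,116.1390314,113.9299442,111.7263214,109.5323296,107.3521354,105.1899055,103.0498064,100.9360049,98.85266759,96.803961,94.79405183,92.82710669,90.90729221,89.03877503,87.22572176,85.47229905,83.78267352,82.16101179,80.6114805,79.13824628,77.74547575,76.43733555,75.2179923,74.09161262,73.06236316,72.13441054,71.31192139,70.59906233,70,69.4628796,68.93316335,68.41099339,67.89651185,67.38986088,66.89118261,66.40061919,65.91831276,65.44440545,64.97903941,64.52235677,64.07449968,63.63561028,63.20583069,62.78530307,62.37416956,61.97257229,61.5806534,61.19855504,60.82641934,60.46438844,60.11260449,59.77120961,59.44034596,59.12015567,58.81078089,58.51236374,58.22504638,57.94897094,57.68427956,57.43111438,57.18961754,56.95993118,56.74219744,56.53655846,56.34315638,56.16213334,55.99363148,55.83779294,55.69475985,55.56467437,55.44767862,55.34391475,55.2535249,55.17665121,55.11343581,55.06402085,55.02854847,55.00716081,55
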