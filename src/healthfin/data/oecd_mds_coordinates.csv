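country,V1,V2,V3,distance_to_reference,financing_cluster
Türkiye,2.60686351,-1.48837451,1.22595615,0.0000000,3
Colombia,1.68359451,-1.47499168,0.96389713,0.9598332,3
Poland,1.57775977,-0.37795287,0.81516205,1.5687073,3
Slovak Republic,1.62645642,-0.57082212,0.08959264,1.7590971,3
Estonia,1.80253676,-0.27724785,0.22987603,1.7623691,3
Costa Rica,1.66012298,-0.28244396,0.30918749,1.7863513,3
Czech Republic,1.35451798,-1.35228721,-0.46413265,2.1079111,3
Israel,0.68799358,0.08894252,1.17248421,2.4845221,3
Hungary,1.33055360,0.48151694,0.33270790,2.5114402,3
Luxembourg,0.57218396,-1.49709516,-0.32817192,2.5603342,1
New Zealand,0.10398026,-1.11202667,0.08886877,2.7747126,1
Mexico,2.03880990,1.22766345,1.23306845,2.7748149,3
Lithuania,1.62047258,0.87988406,0.09791071,2.8025171,3
Slovenia,-0.32104388,-1.46471832,1.39608128,2.9329412,1
Latvia,1.67391985,1.42167364,0.45198355,3.1524273,3
Ireland,-0.58892275,-1.17103224,0.92631046,3.2254524,1
Iceland,0.32062286,-0.24863449,-1.10009040,3.4891753,1
United Kingdom,-0.28975994,-0.69157732,-0.65800621,3.5460721,1
Japan,-0.07276524,-1.00637741,-1.08756349,3.5728287,1
Spain,0.02900125,0.80013876,-0.10250508,3.6942491,2
Finland,-0.15346012,0.15706338,-0.67067605,3.7314965,1
Chile,0.81366619,1.78220808,0.51883361,3.7963521,2
Italy,0.38567287,0.87195127,-0.78809575,3.8159181,2
Korea,0.83013823,2.07935416,0.64173353,4.0282449,2
Netherlands,-1.18842246,-1.57745995,-0.25309022,4.0742742,1
Denmark,-0.40580210,-0.62514418,-1.60042234,4.2201583,1
Australia,-1.38865136,0.03677644,0.89799282,4.2892639,1
Sweden,-0.28407473,-0.40060479,-1.79008988,4.3170940,1
Germany,-1.14212493,-0.85653400,-1.18160117,4.5000521,1
France,-1.70945243,-1.65849439,-0.07829307,4.5122711,1
Portugal,-0.38573497,1.85998987,0.34118139,4.5771187,2
Greece,0.50915496,2.40915511,-0.10437567,4.6217855,2
Norway,-0.40755403,-0.17281518,-2.15469648,4.7165901,1
Canada,-2.12850913,-0.32951023,0.95570393,4.8825973,1
Austria,-1.44752663,0.90417469,-0.77904909,5.1168757,2
Belgium,-1.12286276,1.24849173,-1.09319155,5.1749146,2
Switzerland,-2.62471138,2.68573744,-0.35187606,6.8762011,2
United States,-7.56664320,-0.29857702,1.89739498,10.2648277,4
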